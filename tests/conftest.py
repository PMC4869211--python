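from datetime import datetime, timezone

import pytest

from pharmwatch.synthetic import GeneratorConfig, generate_corpus
from pharmwatch.types import Tweet


def make_tweet(tweet_id="t1", text="hello world", user_id="u1",
               when=datetime(2012, 1, 1, tzinfo=timezone.utc), **kw) -> Tweet:
    return Tweet(tweet_id, text, when, user_id, **kw)


#: first-person treatment tweets spanning the rating scale, used to pin down
#: tokenizer, feature, and language-detector behavior on realistic text.
EXAMPLE_TWEETS = {
    5: "Hey guys I m officially undetectable!!!! Take that #hiv! CD4 went up bout 150 pts also! yaya!! #atripla",
    4: "Whoever invented Atripla (and it s component parts - it s three drugs in one) are geniuses. I love you.",
    3: "and more exciting and totally separate from this weekend, I am moving drug combinations from Atripla.",
    2: "I hear Truvada makes you fat like a Tellytubby. I am soooooo excited to finally be able to look like my hero, Tinky Winky!",
    1: "@TheBodyDotCom Taking Good food #nutrition as part of myother side effects.",
    0: "So,you better all get started taking Truvada (like I already do). It s OK, coz the FDA say so. hmmmm",
    -1: "#Atripla vs #HIV These meds seem to be getting short andwas still flying.",
    -2: "Atripla is a B**CH when you have to be up early in thefor 6 hours!",
    -3: "Oh boy here goes that feeling I hate.... #Atripla",
    -4: "I think I ll pass on the Atripla again today though. I feel weak but my future is so bleak I just want to waste away.",
}


@pytest.fixture(scope="session")
def small_corpus():
    """A 5000-tweet labeled synthetic stream shared across read-only tests."""
    cfg = GeneratorConfig(n_tweets=5000, n_users=400, n_community_users=64, seed=42)
    tweets, users, edges, truth = generate_corpus(cfg)
    return cfg, tweets, users, edges, truth
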