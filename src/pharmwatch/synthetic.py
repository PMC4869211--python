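"""Synthetic labeled tweet corpora with the statistical structure of the
keyword-matched stream the pipeline is built for.

The generated stream is dominated by noise: link/news/retail tweets carrying
exactly the tokens the exclusion cascade targets, an "FTC"-commerce
component colliding with the drug-name keyword FTC, off-topic filler, and a
foreign-language token-salad contamination. A rare signal class consists of
first-person treatment reports built from sentiment-keyed templates that
always name a drug, optionally name a side effect, and carry an integer
ground-truth sentiment in [-5, 5]. Users split into a signal community with
denser, more reciprocal follow ties, and a background population.

Every noise-template token targeted by the cascade is drawn from the exact
exclusion token lists in :mod:`pharmwatch.filtering`, so filter tests are
aligned by construction. Ground truth is recorded for every tweet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np

from ._util import spawn_rngs
from .filtering import DRUG_KEYWORDS, FOREIGN_TOKENS
from .types import RaterAnnotation, Tweet, UserProfile

SENTIMENT_VALUES = tuple(range(-5, 6))

#: default probabilities over sentiment values -5..5 — neutral-heavy with a
#: slight negative skew (mean -0.175), matching a stream where most relevant
#: tweets are matter-of-fact and complaints outnumber praise.
DEFAULT_SENTIMENT_DISTRIBUTION = (
    0.0, 0.02, 0.05, 0.08, 0.11, 0.58, 0.07, 0.04, 0.03, 0.015, 0.005
)

DEFAULT_SIDE_EFFECTS = (
    "insomnia", "vivid dreams", "nightmares", "dizziness", "nausea",
    "vomiting", "rash", "headache", "fatigue", "stomach cramps",
    "night sweats", "kidney pain", "weakness", "depression",
)

#: heavier weight on the drugs that dominate real mention trends.
_DRUG_WEIGHTS = {
    "Atripla": 0.30, "Truvada": 0.20, "Sustiva": 0.08, "Complera": 0.06,
    "Isentress": 0.05, "Norvir": 0.04, "Kaletra": 0.04,
}

_POSITIVE_TEMPLATES = (
    "whoever invented {drug} must be a genius, i love it",
    "officially undetectable on my {drug}, so happy with these results",
    "my doctor switched me to {drug} and i feel so much better now",
    "one year on {drug} and my labs look great, grateful tonight",
)
_NEUTRAL_TEMPLATES = (
    "started {drug} this morning, we will see how it goes",
    "taking my {drug} with dinner as usual before bed",
    "picked up my {drug} refill at the pharmacy today",
    "switching my combination from {drug} next month, just routine",
)
_NEGATIVE_TEMPLATES = (
    "ugh {drug} gives me {se}, i hate this feeling",
    "i think i will skip my {drug} tonight, the {se} is too much",
    "here goes that {se} feeling i hate again, thanks {drug}",
    "{drug} is rough when you have to be up early, the {se} never stops",
)
_NO_EFFECT_SUFFIX = ", no side effects so far and feeling fine"

# Noisy-template tokens (t.co, bit.ly, http, news, buy, free, HIV prefix, FTC)
# come verbatim from the cascade's exclusion lists.
_NOISY_TEMPLATES = (
    "new study about {kw} released today t.co {slug}",
    "read this report on {kw} bit.ly {slug}",
    "latest on {kw} research http {slug}",
    "news update: {kw} trial results published this week",
    "buy {kw} online today, free shipping worldwide {slug}",
    "HIV treatment options seminar announced for clinicians",
    "FTC settlement over giftcard promotions announced by regulators",
    "win a giftcard in our sweepstakes, details inside {slug}",
)
_CLEAN_KEYWORD_TEMPLATES = (
    "the doctor discussed {kw} at the clinic seminar yesterday",
    "researchers compared {kw} with older regimens in that cohort",
    "the panel recommended {kw} for some patients this spring",
    "pharmacies reported steady stocks of {kw} this quarter",
)
_OFFTOPIC_TEMPLATES = (
    "going for a run then coffee with friends later",
    "that movie was hilarious, cannot stop laughing",
    "traffic this morning was unbelievable, missed my train",
    "weekend plans: hiking, cooking and absolutely nothing",
)

_LOCATIONS = (
    "New York City", "San Francisco", "London", "Cape Town", "Toronto",
    "Chicago", "Sydney",
)

_PREP_EVENT_TEXT = " approved for prevention, starting prep soon"
_PREP_WINDOW = (
    datetime(2012, 5, 1, tzinfo=timezone.utc),
    datetime(2012, 9, 1, tzinfo=timezone.utc),
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic stream.

    The desk-scale default (100,000 tweets, 1% signal) keeps the extreme
    rarity of signal while staying testable; the real stream's ~0.004% would
    need millions of tweets to contain any signal at all.
    """

    n_tweets: int = 100_000
    signal_fraction: float = 0.01
    foreign_fraction: float = 0.05
    noisy_token_fraction: float = 0.85  # share of noise carrying cascade tokens
    keyword_noise_fraction: float = 0.7  # share of clean noise naming a drug
    drug_vocabulary: tuple[str, ...] = DRUG_KEYWORDS
    side_effect_vocabulary: tuple[str, ...] = DEFAULT_SIDE_EFFECTS
    sentiment_distribution: tuple[float, ...] = DEFAULT_SENTIMENT_DISTRIBUTION
    time_range: tuple[datetime, datetime] = (
        datetime(2010, 9, 9, tzinfo=timezone.utc),
        datetime(2013, 8, 28, tzinfo=timezone.utc),
    )
    n_users: int = 2000
    n_community_users: int = 256
    within_community_follow_prob: float = 0.01
    background_follow_prob: float = 0.001
    reciprocity_prob: float = 0.5
    no_effect_fraction: float = 0.13  # positive reports noting good tolerance
    retweet_fraction: float = 0.05
    prep_event: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_tweets < 0:
            raise ValueError("n_tweets must be non-negative")
        if self.signal_fraction + self.foreign_fraction > 1 + 1e-12:
            raise ValueError("signal_fraction + foreign_fraction must be <= 1")
        for p in (self.signal_fraction, self.foreign_fraction, self.noisy_token_fraction,
                  self.within_community_follow_prob, self.background_follow_prob,
                  self.reciprocity_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.sentiment_distribution) - 1.0) > 1e-9:
            raise ValueError("sentiment distribution must sum to 1")
        if len(self.sentiment_distribution) != 11:
            raise ValueError("sentiment distribution needs 11 entries for values -5..5")
        if self.time_range[0] >= self.time_range[1]:
            raise ValueError("time_range start must precede end")
        if self.signal_fraction > 0 and (
            not self.drug_vocabulary or not self.side_effect_vocabulary
        ):
            raise ValueError("signal generation requires drug and side-effect vocabularies")
        if self.n_users <= 0:
            raise ValueError("n_users must be positive")


@dataclass
class GroundTruth:
    truth_class: dict[str, str] = field(default_factory=dict)
    category: dict[str, int] = field(default_factory=dict)  # 1..4 rater scheme
    drugs: dict[str, list[str]] = field(default_factory=dict)
    side_effects: dict[str, list[str]] = field(default_factory=dict)
    sentiment: dict[str, int] = field(default_factory=dict)
    no_side_effect_report: set[str] = field(default_factory=set)
    in_community: dict[str, bool] = field(default_factory=dict)


def _drug_weights(drugs: Sequence[str]) -> np.ndarray:
    named = sum(w for d, w in _DRUG_WEIGHTS.items() if d in drugs)
    others = [d for d in drugs if d not in _DRUG_WEIGHTS]
    rest = max(0.0, 1.0 - named)
    w = np.array([
        _DRUG_WEIGHTS.get(d, rest / len(others) if others else 0.0) for d in drugs
    ])
    return w / w.sum()


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[Tweet], list[UserProfile], list[tuple[str, str]], GroundTruth]:
    """Generate (tweets, users, follow edges, ground truth) for the config.

    Deterministic per seed; class proportions hit the config values within
    binomial sampling error; timestamps are uniform over the time range.
    """
    config.validate()
    rng_class, rng_text, rng_users, rng_edges, rng_time = spawn_rngs(config.seed, 5)

    n = config.n_tweets
    classes = rng_class.choice(
        3,
        size=n,
        p=[config.signal_fraction, config.foreign_fraction,
           1.0 - config.signal_fraction - config.foreign_fraction],
    )  # 0=signal, 1=foreign, 2=noise
    start, end = config.time_range
    span = (end - start).total_seconds()
    offsets = np.sort(rng_time.uniform(0.0, span, size=n))
    times = [start + timedelta(seconds=float(s)) for s in offsets]

    users = _make_users(config, rng_users)
    community = [u.user_id for u in users if u.in_community]
    background = [u.user_id for u in users if not u.in_community] or [u.user_id for u in users]

    truth = GroundTruth(in_community={u.user_id: u.in_community for u in users})
    tweets: list[Tweet] = []
    drug_w = _drug_weights(config.drug_vocabulary)
    sentiments = rng_text.choice(SENTIMENT_VALUES, size=n, p=config.sentiment_distribution)

    for i in range(n):
        tid = f"t{i:07d}"
        cls = classes[i]
        if cls == 0:
            text, author = _make_signal(
                tid, config, rng_text, drug_w, int(sentiments[i]), community, times[i], truth
            )
        elif cls == 1:
            text, author = _make_foreign(tid, config, rng_text, background, truth)
        else:
            text, author = _make_noise(tid, config, rng_text, background, truth)
        is_rt = False
        if cls == 0 and rng_text.random() < config.retweet_fraction:
            text = f"RT @{rng_text.choice(background)}: {text}"
            is_rt = True
        tweets.append(Tweet(tid, text, times[i], author, truth.truth_class[tid], is_rt))

    edges = _make_edges(config, users, rng_edges)
    return tweets, users, edges, truth


def _make_users(config: GeneratorConfig, rng: np.random.Generator) -> list[UserProfile]:
    n_comm = min(config.n_community_users, config.n_users)
    profiles = []
    # platform-wide follower counts: heavy-tailed lognormal with mean ~2300
    mu = math.log(2300.0) - 0.5
    counts = rng.lognormal(mean=mu, sigma=1.0, size=config.n_users).astype(int)
    comm_gender_p = np.array([0.482, 0.162, 0.356])
    bg_gender_p = np.array([0.40, 0.40, 0.20])
    genders = ("male", "female", "unidentified")
    for j in range(config.n_users):
        in_comm = j < n_comm
        gender = rng.choice(genders, p=comm_gender_p if in_comm else bg_gender_p)
        location = str(rng.choice(_LOCATIONS)) if rng.random() < 0.5 else None
        profiles.append(
            UserProfile(f"u{j:05d}", int(counts[j]), str(gender), location, in_comm)
        )
    return profiles


def _make_signal(tid, config, rng, drug_w, sentiment, community, when, truth):
    drug = str(rng.choice(config.drug_vocabulary, p=drug_w))
    if sentiment > 0:
        template = _POSITIVE_TEMPLATES[rng.integers(len(_POSITIVE_TEMPLATES))]
    elif sentiment == 0:
        template = _NEUTRAL_TEMPLATES[rng.integers(len(_NEUTRAL_TEMPLATES))]
    else:
        template = _NEGATIVE_TEMPLATES[rng.integers(len(_NEGATIVE_TEMPLATES))]
    effects: list[str] = []
    if sentiment < 0 and config.side_effect_vocabulary:
        effects = [str(rng.choice(config.side_effect_vocabulary))]
    text = template.format(drug=drug, se=effects[0] if effects else "")
    if sentiment > 0 and rng.random() < config.no_effect_fraction:
        text += _NO_EFFECT_SUFFIX
        truth.no_side_effect_report.add(tid)
    if (
        config.prep_event
        and drug == "Truvada"
        and _PREP_WINDOW[0] <= when < _PREP_WINDOW[1]
        and rng.random() < 0.4
    ):
        text += _PREP_EVENT_TEXT
    truth.truth_class[tid] = "signal"
    truth.category[tid] = 1
    truth.drugs[tid] = [drug]
    truth.side_effects[tid] = effects
    truth.sentiment[tid] = sentiment
    return text, str(rng.choice(community))


def _make_noise(tid, config, rng, background, truth):
    kw = str(rng.choice(config.drug_vocabulary)) if config.drug_vocabulary else "Atripla"
    slug = f"x{rng.integers(10**6):06d}"
    if rng.random() < config.noisy_token_fraction:
        template = _NOISY_TEMPLATES[rng.integers(len(_NOISY_TEMPLATES))]
        category = 3
    elif rng.random() < config.keyword_noise_fraction:
        template = _CLEAN_KEYWORD_TEMPLATES[rng.integers(len(_CLEAN_KEYWORD_TEMPLATES))]
        category = 2
    else:
        template = _OFFTOPIC_TEMPLATES[rng.integers(len(_OFFTOPIC_TEMPLATES))]
        category = 3
    text = template.format(kw=kw, slug=slug)
    truth.truth_class[tid] = "noise"
    truth.category[tid] = category
    truth.drugs[tid] = []
    truth.side_effects[tid] = []
    return text, str(rng.choice(background))


def _make_foreign(tid, config, rng, background, truth):
    n_tok = int(rng.integers(6, 13))
    words = list(rng.choice(FOREIGN_TOKENS, size=n_tok))
    if config.drug_vocabulary and rng.random() < 0.5:
        words.insert(int(rng.integers(len(words) + 1)), str(rng.choice(config.drug_vocabulary)))
    truth.truth_class[tid] = "foreign"
    truth.category[tid] = 4
    truth.drugs[tid] = []
    truth.side_effects[tid] = []
    return " ".join(words), str(rng.choice(background))


def _make_edges(
    config: GeneratorConfig, users: list[UserProfile], rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Follow edges: per unordered community pair, connect with probability
    within_community_follow_prob; connected pairs are mutual with probability
    reciprocity_prob, else one random direction. Background/cross pairs are
    sparser (background_follow_prob) via sparse Poisson sampling.
    """
    ids = [u.user_id for u in users]
    comm = [u.user_id for u in users if u.in_community]
    edges: list[tuple[str, str]] = []
    for i in range(len(comm)):
        for j in range(i + 1, len(comm)):
            if rng.random() < config.within_community_follow_prob:
                if rng.random() < config.reciprocity_prob:
                    edges.append((comm[i], comm[j]))
                    edges.append((comm[j], comm[i]))
                elif rng.random() < 0.5:
                    edges.append((comm[i], comm[j]))
                else:
                    edges.append((comm[j], comm[i]))
    n_total_pairs = len(ids) * (len(ids) - 1) // 2
    n_comm_pairs = len(comm) * (len(comm) - 1) // 2
    n_bg = rng.poisson(config.background_follow_prob * (n_total_pairs - n_comm_pairs))
    comm_set = set(comm)
    made = 0
    while made < n_bg:
        a, b = rng.choice(len(ids), size=2, replace=False)
        ua, ub = ids[int(a)], ids[int(b)]
        if ua in comm_set and ub in comm_set:
            continue
        edges.append((ua, ub))
        if rng.random() < config.reciprocity_prob:
            edges.append((ub, ua))
        made += 1
    return edges


def simulate_raters(
    tweets: Sequence[Tweet],
    truth: GroundTruth,
    n_raters: int = 2,
    error_rate: float = 0.1,
    seed: int = 0,
    sentiment_noise: float = 0.0,
) -> list[RaterAnnotation]:
    """Independent category raters with a symmetric-uniform error model.

    Each rater reports the true category with probability 1 - error_rate,
    otherwise a uniformly random *other* category; with two raters the
    expected pairwise agreement is (1-e)^2 + e^2/3. Sentiment (present for
    signal tweets) is reported as truth plus an integer +-1 perturbation with
    probability `sentiment_noise`, clipped to [-5, 5]. Drug and side-effect
    tags are transcribed when the rater judges the tweet personal-medication.
    """
    if n_raters < 2:
        raise ValueError("at least 2 raters required")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if not 0 <= sentiment_noise <= 1:
        raise ValueError("sentiment_noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    annotations: list[RaterAnnotation] = []
    for t in tweets:
        true_cat = truth.category[t.tweet_id]
        for r in range(n_raters):
            if rng.random() < error_rate:
                cat = int(rng.choice([c for c in (1, 2, 3, 4) if c != true_cat]))
            else:
                cat = true_cat
            sentiment = None
            if t.tweet_id in truth.sentiment:
                s = truth.sentiment[t.tweet_id]
                if rng.random() < sentiment_noise:
                    s += int(rng.choice((-1, 1)))
                sentiment = int(np.clip(s, -5, 5))
            drugs: list[str] = []
            effects: list[str] = []
            if cat == 1:
                drugs = list(truth.drugs.get(t.tweet_id, []))
                effects = list(truth.side_effects.get(t.tweet_id, []))
                if t.tweet_id in truth.no_side_effect_report:
                    effects.append("no side effects")
            annotations.append(
                RaterAnnotation(t.tweet_id, f"r{r}", cat, sentiment, effects, drugs)
            )
    return annotations


def drifting_sentiment_series(
    n: int,
    time_range: tuple[datetime, datetime],
    mean_start: float,
    mean_end: float,
    sd: float = 1.0,
    seed: int = 0,
) -> list[tuple[datetime, int]]:
    """Timestamped integer ratings whose generating mean drifts linearly.

    Timestamps are evenly spread over the range; each rating is a rounded,
    clipped normal draw around the drifting mean. The true mean at time t is
    mean_start + (mean_end - mean_start) * frac(t), with frac the fractional
    position of t in the range — the oracle for bin-tracking tests.
    """
    rng = np.random.default_rng(seed)
    start, end = time_range
    span = (end - start).total_seconds()
    out = []
    for i in range(n):
        frac = (i + 0.5) / n
        t = start + timedelta(seconds=frac * span)
        mean = mean_start + (mean_end - mean_start) * frac
        rating = int(np.clip(round(rng.normal(mean, sd)), -5, 5))
        out.append((t, rating))
    return out
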