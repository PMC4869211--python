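import math

import numpy as np
import pytest

from pharmwatch.filtering import (
    DEFAULT_STAGES,
    DRUG_KEYWORDS,
    STAGE3_TOKENS,
    tokenize,
)
from pharmwatch.features import PERSONAL_PRONOUNS
from pharmwatch.synthetic import (
    GeneratorConfig,
    drifting_sentiment_series,
    generate_corpus,
    simulate_raters,
)


def _small(n=2000, **kw):
    defaults = dict(n_tweets=n, n_users=200, n_community_users=32, seed=1)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestGenerateCorpus:
    def test_empty(self):
        tweets, users, edges, truth = generate_corpus(_small(0))
        assert tweets == [] and truth.truth_class == {}

    def test_signal_count_within_binomial_bound(self):
        n, p = 10_000, 0.01
        tweets, _, _, truth = generate_corpus(_small(n, signal_fraction=p, seed=7))
        n_signal = sum(1 for c in truth.truth_class.values() if c == "signal")
        assert abs(n_signal - n * p) <= 3 * math.sqrt(n * p * (1 - p))

    def test_pure_signal_construction(self):
        tweets, _, _, truth = generate_corpus(_small(300, signal_fraction=1.0,
                                                     foreign_fraction=0.0))
        drugs = {d.lower() for d in DRUG_KEYWORDS}
        for t in tweets:
            toks = tokenize(t.text)
            assert toks & drugs, t.text
            assert toks & PERSONAL_PRONOUNS, t.text

    def test_truth_recorded_for_all_tweets(self):
        tweets, _, _, truth = generate_corpus(_small(500))
        assert {t.tweet_id for t in tweets} == set(truth.truth_class)
        assert set(truth.category) == set(truth.truth_class)

    def test_timestamps_within_range_and_sorted(self):
        cfg = _small(500)
        tweets, _, _, _ = generate_corpus(cfg)
        times = [t.created_at for t in tweets]
        assert times == sorted(times)
        assert all(cfg.time_range[0] <= t < cfg.time_range[1] for t in times)

    def test_same_seed_byte_identical(self):
        def serialize():
            tweets, users, edges, _ = generate_corpus(_small(800, seed=9))
            return (
                "\n".join(f"{t.tweet_id}\t{t.text}\t{t.created_at}\t{t.user_id}" for t in tweets),
                [(u.user_id, u.follower_count, u.gender, u.location) for u in users],
                edges,
            )

        assert serialize() == serialize()

    def test_signal_avoids_cascade_tokens(self):
        tweets, _, _, truth = generate_corpus(_small(2000, seed=3))
        bad = set(STAGE3_TOKENS) | {"http", "news", "t.co", "bit.ly"}
        for t in tweets:
            if truth.truth_class[t.tweet_id] == "signal":
                assert not (tokenize(t.text) & bad), t.text

    def test_noise_templates_drawn_from_exclusion_lists(self):
        cfg = _small(3000, noisy_token_fraction=1.0, seed=5)
        tweets, _, _, truth = generate_corpus(cfg)
        stage_tokens = {r.pattern for rules in DEFAULT_STAGES for r in rules
                        if r.mode == "contains_token"}
        for t in tweets:
            if truth.truth_class[t.tweet_id] != "noise":
                continue
            toks = tokenize(t.text)
            hits_cascade = (
                bool(toks & stage_tokens)
                or t.text.lstrip().lower().startswith("hiv")
                or "ftc" in toks
                or "giftcard" in toks  # keyword-stage casualty, by design
            )
            assert hits_cascade, t.text

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(signal_fraction=0.7, foreign_fraction=0.4).validate()
        with pytest.raises(ValueError):
            GeneratorConfig(sentiment_distribution=(1.0,) * 11).validate()
        with pytest.raises(ValueError):
            GeneratorConfig(signal_fraction=0.5, drug_vocabulary=()).validate()

    def test_community_edges_denser_than_background(self):
        cfg = _small(200, n_users=400, n_community_users=100,
                     within_community_follow_prob=0.05, background_follow_prob=0.001, seed=2)
        _, users, edges, _ = generate_corpus(cfg)
        comm = {u.user_id for u in users if u.in_community}
        n_comm = sum(1 for a, b in edges if a in comm and b in comm)
        n_bg = len(edges) - n_comm
        comm_pairs = len(comm) * (len(comm) - 1)
        bg_pairs = len(users) * (len(users) - 1) - comm_pairs
        assert n_comm / comm_pairs > n_bg / bg_pairs


class TestSimulateRaters:
    def _setup(self, n=500, seed=4):
        tweets, _, _, truth = generate_corpus(_small(n, seed=seed))
        return tweets, truth

    @staticmethod
    def agreement(annotations):
        by_tweet = {}
        for a in annotations:
            by_tweet.setdefault(a.tweet_id, []).append(a.category)
        agree = sum(1 for cats in by_tweet.values() if cats[0] == cats[1])
        return agree / len(by_tweet)

    def test_zero_error_full_agreement(self):
        tweets, truth = self._setup()
        anns = simulate_raters(tweets, truth, error_rate=0.0, seed=0)
        assert self.agreement(anns) == 1.0

    def test_zero_noise_reproduces_truth(self):
        tweets, truth = self._setup()
        anns = simulate_raters(tweets, truth, error_rate=0.0, seed=0, sentiment_noise=0.0)
        for a in anns:
            assert a.category == truth.category[a.tweet_id]
            if a.tweet_id in truth.sentiment:
                assert a.sentiment == truth.sentiment[a.tweet_id]
            if truth.category[a.tweet_id] == 1:
                assert a.drugs == truth.drugs[a.tweet_id]

    def test_agreement_matches_closed_form(self):
        # two raters, error rate e: agree iff both right or both wrong alike
        e = 0.2
        expected = (1 - e) ** 2 + e**2 / 3
        tweets, truth = self._setup(n=4000, seed=8)
        anns = simulate_raters(tweets, truth, error_rate=e, seed=1)
        se = math.sqrt(expected * (1 - expected) / len(tweets))
        assert abs(self.agreement(anns) - expected) < 3 * se

    def test_sentiment_noise_clipped_and_integer(self):
        tweets, truth = self._setup()
        anns = simulate_raters(tweets, truth, error_rate=0.0, seed=2, sentiment_noise=1.0)
        for a in anns:
            if a.sentiment is not None:
                assert isinstance(a.sentiment, int) and -5 <= a.sentiment <= 5

    def test_invalid_params(self):
        tweets, truth = self._setup(50)
        with pytest.raises(ValueError):
            simulate_raters(tweets, truth, n_raters=1)
        with pytest.raises(ValueError):
            simulate_raters(tweets, truth, error_rate=1.0)


def test_drifting_series_mean_tracks_drift():
    from datetime import datetime, timezone

    rng_range = (datetime(2011, 1, 1, tzinfo=timezone.utc),
                 datetime(2011, 12, 31, tzinfo=timezone.utc))
    rated = drifting_sentiment_series(4000, rng_range, -2.0, 2.0, sd=1.0, seed=0)
    first = np.mean([r for _, r in rated[:1000]])
    last = np.mean([r for _, r in rated[-1000:]])
    assert first < -1.0 and last > 1.0
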