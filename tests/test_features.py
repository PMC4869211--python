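import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pharmwatch.features import (
    ClassifierSettings,
    auc,
    calibrate_threshold,
    eval_from_scores,
    evaluate,
    extract_features,
    feature_matrix,
    fit_token_models,
    threshold_at_efficiency,
    train,
)
from pharmwatch.synthetic import GeneratorConfig, generate_corpus

from conftest import EXAMPLE_TWEETS, make_tweet


def _corpus(texts):
    return [make_tweet(f"t{i}", t) for i, t in enumerate(texts)]


class TestTokenModels:
    def test_identical_corpora_empty_common_sets(self):
        tweets = _corpus(["a b c", "c d", "a d"])
        models = fit_token_models(tweets, tweets, top_k=3)
        assert models.common_signal == frozenset() and models.common_noise == frozenset()

    def test_single_tweet_bigram(self):
        models = fit_token_models(_corpus(["a b"]), _corpus(["x y"]), top_k=1)
        assert set(models.noise_bigram.log_freq) == {("x", "y")}

    def test_generator_corpora_rank_discriminative_tokens(self, small_corpus):
        _, tweets, _, _, truth = small_corpus
        signal = [t for t in tweets if truth.truth_class[t.tweet_id] == "signal"]
        noise = [t for t in tweets if truth.truth_class[t.tweet_id] == "noise"]
        models = fit_token_models(signal, noise, top_k=40)
        assert models.common_signal & {"atripla", "truvada"}
        assert models.common_noise & {"news", "http", "buy"}

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_token_models([], _corpus(["x"]))


@pytest.fixture(scope="module")
def models():
    return fit_token_models(
        _corpus(["i feel weak on my atripla", "my truvada gives me nausea"]),
        _corpus(["news update http buy now", "breaking news report today"]),
        top_k=5,
    )


class TestExtractFeatures:

    def test_first_person_report_counts_pronouns(self, models):
        fv = extract_features(make_tweet(text=EXAMPLE_TWEETS[-4]), models)
        assert fv.personalcount >= 3
        assert fv.ncharacters == len(EXAMPLE_TWEETS[-4])

    def test_empty_token_tweet_floors(self, models):
        fv = extract_features(make_tweet(text="!!! ... ???"), models)
        assert fv.personalcount == 0 and fv.tagnoun == 0
        assert fv.is_english == 0.0
        assert fv.ncharacters == len("!!! ... ???")
        # likelihood features sit at the unseen-token smoothing floor
        assert fv.sis_noise == pytest.approx(models.noise_unigram.log_unseen)

    def test_noise_topk_tweet(self, models):
        toks = sorted(models.common_noise)
        assert toks, "fixture must yield a non-empty noise top-K"
        fv = extract_features(make_tweet(text=" ".join(toks)), models)
        assert fv.common_noise == len(toks)
        assert fv.common_signal == 0

    def test_purity(self, models):
        t = make_tweet(text=EXAMPLE_TWEETS[5])
        assert extract_features(t, models) == extract_features(t, models)

    def test_likelihoods_length_normalized(self, models):
        short = extract_features(make_tweet(text="my atripla"), models)
        long = extract_features(make_tweet(text="my atripla " * 10), models)
        assert short.sis_signal == pytest.approx(long.sis_signal)


class TestCalibrateThreshold:
    def test_decile_scores_target_90(self):
        scores = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        assert threshold_at_efficiency(scores, 0.9) == pytest.approx(0.2)

    def test_target_one_gives_minimum(self):
        assert threshold_at_efficiency([0.4, 0.9, 0.2], 1.0) == pytest.approx(0.2)

    def test_constant_scores(self):
        for target in (0.1, 0.5, 1.0):
            assert threshold_at_efficiency([0.7] * 5, target) == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            threshold_at_efficiency([], 0.9)

    @given(
        scores=st.lists(st.floats(0, 1, allow_nan=False).map(lambda x: round(x, 2)),
                        min_size=1, max_size=200),
        target=st.floats(0.05, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_exhaustive_enumeration(self, scores, target):
        tau = threshold_at_efficiency(scores, target)
        arr = np.asarray(scores)
        feasible = [c for c in np.unique(arr) if np.mean(arr >= c) >= target]
        assert tau == pytest.approx(max(feasible))
        assert np.mean(arr >= tau) >= target  # guaranteed efficiency


class TestEvaluate:
    def test_reference_operating_point(self):
        # 481 of 603 noise below tau, 26 of 30 signal at/above tau
        tau = 0.45
        noise = np.concatenate([np.full(481, 0.1), np.full(122, 0.9)])
        signal = np.concatenate([np.full(26, 0.9), np.full(4, 0.1)])
        res = eval_from_scores(signal, noise, tau)
        assert round(100 * res.noise_rejection, 1) == 79.8
        assert round(100 * res.signal_efficiency) == 87

    def test_zero_threshold_full_efficiency(self):
        res = eval_from_scores(np.array([0.0, 0.5, 1.0]), np.array([0.2]), 0.0)
        assert res.signal_efficiency == 1.0

    def test_roc_monotone(self):
        rng = np.random.default_rng(5)
        res = eval_from_scores(rng.beta(5, 2, 100), rng.beta(2, 5, 100), 0.5)
        effs = [e for _, e, _ in res.roc]
        rejs = [r for _, _, r in res.roc]
        assert all(a >= b for a, b in zip(effs, effs[1:]))  # eff non-increasing in tau
        assert all(a <= b for a, b in zip(rejs, rejs[1:]))  # rejection non-decreasing


class TestTrain:
    def test_separable_features_perfect_training_auc(self):
        rng = np.random.default_rng(0)
        Xs = rng.normal(5, 0.3, size=(40, 9))
        Xn = rng.normal(-5, 0.3, size=(40, 9))
        clf = train(Xs, Xn, ClassifierSettings(seed=0))
        assert auc(clf.score(Xs), clf.score(Xn)) == 1.0

    def test_scores_bounded(self):
        rng = np.random.default_rng(1)
        clf = train(rng.normal(1, 1, (30, 9)), rng.normal(0, 1, (30, 9)))
        s = clf.score(rng.normal(0, 3, (50, 9)))
        assert np.all((s >= 0) & (s <= 1))

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, size=(400, 9))
        perm = rng.permutation(400)
        clf = train(X[perm[:200]], X[perm[200:]], ClassifierSettings(seed=0))
        held = rng.normal(0, 1, size=(400, 9))
        a = auc(clf.score(held[:200]), clf.score(held[200:]))
        se = np.sqrt(1 / 12) / np.sqrt(200)  # conservative AUC standard error
        assert abs(a - 0.5) < 3 * se + 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train(np.empty((0, 9)), np.ones((5, 9)))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        Xs, Xn = rng.normal(1, 1, (30, 9)), rng.normal(0, 1, (30, 9))
        s1 = train(Xs, Xn, ClassifierSettings(seed=9)).score(Xn)
        s2 = train(Xs, Xn, ClassifierSettings(seed=9)).score(Xn)
        assert np.array_equal(s1, s2)


def test_held_out_auc_on_generator_corpus():
    """Featurize -> train on one synthetic stream, evaluate on a fresh one."""
    def labeled(seed):
        cfg = GeneratorConfig(n_tweets=3000, n_users=300, n_community_users=48, seed=seed)
        tweets, _, _, truth = generate_corpus(cfg)
        sig = [t for t in tweets if truth.truth_class[t.tweet_id] == "signal"]
        noi = [t for t in tweets if truth.truth_class[t.tweet_id] == "noise"]
        return sig, noi

    sig_tr, noi_tr = labeled(11)
    sig_te, noi_te = labeled(12)
    models = fit_token_models(sig_tr, noi_tr)
    feats = lambda ts: [extract_features(t, models) for t in ts]
    clf = train(feats(sig_tr), feats(noi_tr), ClassifierSettings(seed=0))
    a = auc(clf.score(feats(sig_te)), clf.score(feats(noi_te)))
    assert a > 0.9

    tau = calibrate_threshold(clf, feats(sig_te), 0.9)
    res = evaluate(clf, tau, feats(sig_te), feats(noi_te))
    assert res.signal_efficiency >= 0.9
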