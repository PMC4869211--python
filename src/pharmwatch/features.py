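"""The nine per-tweet features, classifier training, and threshold calibration.

Each tweet is reduced to nine numbers with separation power between objective
information (news, retail, links) and subjective first-person reports:

* ``personalcount`` — occurrences of first/second-person pronouns;
* ``tagnoun`` — heuristic count of open-class noun-like tokens;
* ``sis_signal`` / ``sis_noise`` — length-normalized unigram log-likelihood
  of the tweet under a smoothed signal / noise token model;
* ``bigrams_noise`` — length-normalized bigram log-likelihood under the noise
  model;
* ``is_english`` — fraction of tokens that are English function words;
* ``common_signal`` / ``common_noise`` — tokens drawn from the top-K most
  frequent tokens of each class (shared top-K tokens removed from both sets);
* ``ncharacters`` — raw character length.

A supervised classifier maps the vector to a score in [0, 1] (higher = more
signal-like); the working threshold is then calibrated on held-out signal so
that a target fraction (default 90%) of true signal scores at or above it,
and the classifier is judged by its noise rejection at that fixed signal
efficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .filtering import ENGLISH_FUNCTION_WORDS, tokenize_ordered
from .types import Tweet

PERSONAL_PRONOUNS: frozenset[str] = frozenset(
    {"i", "me", "my", "mine", "we", "us", "our", "you", "your"}
)

# Crude open-class noun proxy: not a function word or pronoun, not numeric,
# and not carrying an adverb/verb inflection suffix. A statistical POS tagger
# would be better; for short informal tweets this keeps the feature cheap,
# deterministic and dependency-free, and the classifier only needs its
# separation power, not its absolute accuracy.
_NON_NOUN_SUFFIXES = ("ly", "ing", "ed")

FEATURE_NAMES = (
    "personalcount", "tagnoun", "sis_noise", "sis_signal", "bigrams_noise",
    "is_english", "common_noise", "common_signal", "ncharacters",
)


def count_nouns(text: str) -> int:
    n = 0
    for tok in tokenize_ordered(text):
        if tok in ENGLISH_FUNCTION_WORDS or tok in PERSONAL_PRONOUNS:
            continue
        if tok.replace(".", "").replace("-", "").isdigit():
            continue
        if len(tok) > 4 and tok.endswith(_NON_NOUN_SUFFIXES):
            continue
        n += 1
    return n


@dataclass
class _UnigramModel:
    log_freq: dict[str, float]
    log_unseen: float

    def log_prob(self, token: str) -> float:
        return self.log_freq.get(token, self.log_unseen)


@dataclass
class _BigramModel:
    log_freq: dict[tuple[str, str], float]
    log_unseen: float

    def log_prob(self, bigram: tuple[str, str]) -> float:
        return self.log_freq.get(bigram, self.log_unseen)


def _fit_unigram(token_lists: list[list[str]], pseudo_count: float) -> _UnigramModel:
    counts: dict[str, int] = {}
    for toks in token_lists:
        for t in toks:
            counts[t] = counts.get(t, 0) + 1
    total = sum(counts.values())
    vocab = len(counts) + 1  # +1 unseen bucket
    denom = total + pseudo_count * vocab
    return _UnigramModel(
        {t: math.log((c + pseudo_count) / denom) for t, c in counts.items()},
        math.log(pseudo_count / denom),
    )


def _fit_bigram(token_lists: list[list[str]], pseudo_count: float) -> _BigramModel:
    counts: dict[tuple[str, str], int] = {}
    for toks in token_lists:
        for pair in zip(toks, toks[1:]):
            counts[pair] = counts.get(pair, 0) + 1
    total = sum(counts.values())
    vocab = len(counts) + 1
    denom = total + pseudo_count * vocab
    return _BigramModel(
        {b: math.log((c + pseudo_count) / denom) for b, c in counts.items()},
        math.log(pseudo_count / denom),
    )


@dataclass
class TokenModels:
    signal_unigram: _UnigramModel
    noise_unigram: _UnigramModel
    noise_bigram: _BigramModel
    common_signal: frozenset[str]
    common_noise: frozenset[str]
    english_words: frozenset[str] = ENGLISH_FUNCTION_WORDS
    pseudo_count: float = 0.5
    top_k: int = 50


def fit_token_models(
    signal_tweets: Sequence[Tweet],
    noise_tweets: Sequence[Tweet],
    top_k: int = 50,
    pseudo_count: float = 0.5,
) -> TokenModels:
    """Fit the per-class token statistics behind the likelihood and top-K features.

    Top-K sets hold each class's most frequent tokens after removing tokens
    that appear in *both* top-K lists (shared tokens carry no separation
    power). Frequency ties are broken alphabetically for determinism.
    """
    if not signal_tweets or not noise_tweets:
        raise ValueError("both signal and noise training corpora must be non-empty")
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive")
    sig_tokens = [tokenize_ordered(t.text) for t in signal_tweets]
    noi_tokens = [tokenize_ordered(t.text) for t in noise_tweets]

    def top_tokens(token_lists: list[list[str]]) -> list[str]:
        counts: dict[str, int] = {}
        for toks in token_lists:
            for t in toks:
                counts[t] = counts.get(t, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [t for t, _ in ranked[:top_k]]

    top_sig = top_tokens(sig_tokens)
    top_noi = top_tokens(noi_tokens)
    shared = set(top_sig) & set(top_noi)
    return TokenModels(
        signal_unigram=_fit_unigram(sig_tokens, pseudo_count),
        noise_unigram=_fit_unigram(noi_tokens, pseudo_count),
        noise_bigram=_fit_bigram(noi_tokens, pseudo_count),
        common_signal=frozenset(t for t in top_sig if t not in shared),
        common_noise=frozenset(t for t in top_noi if t not in shared),
        pseudo_count=pseudo_count,
        top_k=top_k,
    )


@dataclass(frozen=True)
class FeatureVector:
    personalcount: int
    tagnoun: int
    sis_noise: float
    sis_signal: float
    bigrams_noise: float
    is_english: float
    common_noise: int
    common_signal: int
    ncharacters: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def extract_features(tweet: Tweet, models: TokenModels) -> FeatureVector:
    """Map one tweet to its nine-feature vector (pure and deterministic)."""
    tokens = tokenize_ordered(tweet.text)
    n_tok = max(1, len(tokens))
    bigrams = list(zip(tokens, tokens[1:]))
    n_big = max(1, len(bigrams))
    # token-free tweets sit at the unseen-token smoothing floor
    sis_noise = (
        sum(models.noise_unigram.log_prob(t) for t in tokens) / n_tok
        if tokens else models.noise_unigram.log_unseen
    )
    sis_signal = (
        sum(models.signal_unigram.log_prob(t) for t in tokens) / n_tok
        if tokens else models.signal_unigram.log_unseen
    )
    bigrams_noise = (
        sum(models.noise_bigram.log_prob(b) for b in bigrams) / n_big
        if bigrams else models.noise_bigram.log_unseen
    )
    return FeatureVector(
        personalcount=sum(t in PERSONAL_PRONOUNS for t in tokens),
        tagnoun=count_nouns(tweet.text),
        sis_noise=sis_noise,
        sis_signal=sis_signal,
        bigrams_noise=bigrams_noise,
        is_english=(sum(t in models.english_words for t in tokens) / n_tok) if tokens else 0.0,
        common_noise=sum(t in models.common_noise for t in tokens),
        common_signal=sum(t in models.common_signal for t in tokens),
        ncharacters=len(tweet.text),
    )


def feature_matrix(vectors: Sequence[FeatureVector]) -> np.ndarray:
    return np.vstack([v.as_array() for v in vectors]) if vectors else np.empty((0, 9))


@dataclass
class ClassifierSettings:
    family: str = "logistic"  # logistic (margin-based) | gbm (tree ensemble)
    seed: int = 0
    params: dict = field(default_factory=dict)


@dataclass
class TrainedClassifier:
    model: Pipeline
    settings: ClassifierSettings
    n_signal: int
    n_noise: int
    threshold: float | None = None  # set only by calibrate_threshold

    def score(self, X: np.ndarray | Sequence[FeatureVector]) -> np.ndarray:
        if not isinstance(X, np.ndarray):
            X = feature_matrix(X)
        if len(X) == 0:
            return np.empty(0)
        return self.model.predict_proba(X)[:, 1]


def train(
    signal_features: Sequence[FeatureVector] | np.ndarray,
    noise_features: Sequence[FeatureVector] | np.ndarray,
    settings: ClassifierSettings | None = None,
) -> TrainedClassifier:
    """Fit a binary signal-vs-noise scorer on labeled feature vectors.

    Class imbalance (signal is rare) is handled by balanced class weights.
    The score is the model's probability of the signal class, in [0, 1].
    """
    settings = settings or ClassifierSettings()
    Xs = signal_features if isinstance(signal_features, np.ndarray) else feature_matrix(signal_features)
    Xn = noise_features if isinstance(noise_features, np.ndarray) else feature_matrix(noise_features)
    if len(Xs) == 0 or len(Xn) == 0:
        raise ValueError("training requires examples of both classes")
    X = np.vstack([Xs, Xn])
    y = np.concatenate([np.ones(len(Xs), dtype=int), np.zeros(len(Xn), dtype=int)])
    if settings.family == "logistic":
        clf = LogisticRegression(
            max_iter=2000, class_weight="balanced", random_state=settings.seed,
            **settings.params,
        )
    elif settings.family == "gbm":
        clf = GradientBoostingClassifier(random_state=settings.seed, **settings.params)
    else:
        raise ValueError(f"unknown classifier family {settings.family!r}")
    pipe = Pipeline([("scale", StandardScaler()), ("clf", clf)])
    pipe.fit(X, y)
    return TrainedClassifier(pipe, settings, n_signal=len(Xs), n_noise=len(Xn))


def threshold_at_efficiency(signal_scores: Sequence[float], target_efficiency: float) -> float:
    """Largest threshold keeping at least `target_efficiency` of the signal scores.

    tau is the k-th largest score with k = ceil(target * n); ties resolve
    toward the larger tau (maximal noise rejection at the guaranteed
    efficiency).
    """
    scores = np.asarray(signal_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("calibration requires a non-empty signal score set")
    if not 0 < target_efficiency <= 1:
        raise ValueError("target efficiency must be in (0, 1]")
    k = math.ceil(target_efficiency * scores.size)
    return float(np.sort(scores)[::-1][k - 1])


def calibrate_threshold(
    classifier: TrainedClassifier,
    held_out_signal: Sequence[FeatureVector] | np.ndarray,
    target_efficiency: float = 0.90,
) -> float:
    """Calibrate and install the classifier's working threshold."""
    tau = threshold_at_efficiency(classifier.score(held_out_signal), target_efficiency)
    classifier.threshold = tau
    return tau


@dataclass
class EvalResult:
    signal_efficiency: float
    noise_rejection: float
    roc: list[tuple[float, float, float]]  # (threshold, signal_eff, noise_rej)


def eval_from_scores(
    signal_scores: np.ndarray, noise_scores: np.ndarray, tau: float
) -> EvalResult:
    signal_scores = np.asarray(signal_scores, dtype=float)
    noise_scores = np.asarray(noise_scores, dtype=float)
    if signal_scores.size == 0 or noise_scores.size == 0:
        raise ValueError("evaluation requires non-empty labeled test sets")
    eff = float(np.mean(signal_scores >= tau))
    rej = float(np.mean(noise_scores < tau))
    thresholds = np.unique(np.concatenate([signal_scores, noise_scores, [0.0, 1.0]]))
    roc = [
        (float(t), float(np.mean(signal_scores >= t)), float(np.mean(noise_scores < t)))
        for t in thresholds
    ]
    return EvalResult(eff, rej, roc)


def evaluate(
    classifier: TrainedClassifier,
    tau: float,
    signal_test: Sequence[FeatureVector] | np.ndarray,
    noise_test: Sequence[FeatureVector] | np.ndarray,
) -> EvalResult:
    """Signal efficiency and noise rejection at tau, plus the full ROC sweep."""
    return eval_from_scores(classifier.score(signal_test), classifier.score(noise_test), tau)


def auc(signal_scores: np.ndarray, noise_scores: np.ndarray) -> float:
    """Probability a random signal score exceeds a random noise score (ties 1/2)."""
    from scipy.stats import rankdata

    s = np.asarray(signal_scores, dtype=float)
    n = np.asarray(noise_scores, dtype=float)
    ranks = rankdata(np.concatenate([s, n]))
    return float((ranks[: s.size].sum() - s.size * (s.size + 1) / 2) / (s.size * n.size))
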