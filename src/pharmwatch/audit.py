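"""Statistical audit of candidate exclusion rules.

Before a rule is allowed to discard part of the stream, a random subsample of
rule-matching tweets is hand-labeled. The signal count observed in a
reference sample of size n is scaled to the audit-sample size m under a
Poisson model (lambda = k * m / n, uncertainty sqrt(lambda)); if every one of
r independent audit samples of matching tweets contains zero signal, the
probability of that outcome under the Poisson expectation, exp(-r * lambda),
bounds how likely the rule is to be discarding signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .types import Tweet


@dataclass(frozen=True)
class SampleEstimate:
    """Observed count k in a sample of n, scaled to a target size m."""

    observed: int
    sample_size: int
    target_size: int
    expected: float
    uncertainty: float


def scale_expectation(observed: int, sample_size: int, target_size: int) -> SampleEstimate:
    """Scale a count across sample sizes: lambda = k*m/n, sigma = sqrt(lambda)."""
    if sample_size <= 0 or target_size <= 0:
        raise ValueError("sample_size and target_size must be positive")
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    expected = observed * target_size / sample_size
    return SampleEstimate(observed, sample_size, target_size, expected, math.sqrt(expected))


def loss_probability(estimate: SampleEstimate | float, replicates: int = 1) -> float:
    """P(zero signal in each of `replicates` audit samples) = exp(-r*lambda)."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    lam = estimate.expected if isinstance(estimate, SampleEstimate) else float(estimate)
    if lam < 0:
        raise ValueError("rate must be non-negative")
    return math.exp(-replicates * lam)


def draw_audit_sample(
    tweets: Sequence[Tweet],
    predicate: Callable[[Tweet], bool],
    size: int,
    seed: int,
) -> list[Tweet]:
    """Uniform sample without replacement from the tweets satisfying `predicate`."""
    pool = [t for t in tweets if predicate(t)]
    if size > len(pool):
        raise ValueError(f"sample size {size} exceeds qualifying population {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[i] for i in idx]


def compare_signal_content(
    k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05
) -> tuple[bool, float]:
    """Two-sided exact test of equal signal proportions in two labeled samples.

    Conditions on the total k1+k2: under the null, k1 ~ Binomial(k1+k2,
    n1/(n1+n2)); the p-value sums outcome probabilities no larger than the
    observed one.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    total = k1 + k2
    if total == 0:
        return False, 1.0
    p_null = n1 / (n1 + n2)
    p_value = stats.binomtest(k1, total, p_null, alternative="two-sided").pvalue
    return p_value < alpha, float(p_value)


@dataclass
class AuditDecision:
    rules: str
    estimate: SampleEstimate
    zero_replicates: int
    loss_probability: float
    decision: str  # discard_rule_targets | keep


def make_audit_decision(
    rules: str,
    estimate: SampleEstimate,
    zero_replicates: int,
    max_loss: float = 1e-3,
) -> AuditDecision:
    """Discard the rule's targets iff the signal-loss probability is below `max_loss`.

    `estimate` is the Poisson expectation of signal in one audit sample of
    matching tweets (scaled from a labeled reference sample); `zero_replicates`
    is the number of independent matching samples in which zero signal was
    actually found.
    """
    p_loss = loss_probability(estimate, zero_replicates) if zero_replicates >= 1 else 1.0
    decision = "discard_rule_targets" if p_loss < max_loss else "keep"
    return AuditDecision(rules, estimate, zero_replicates, p_loss, decision)
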