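"""Rater consensus, the sentiment statistic Psi, and side-effect aggregation.

Tweets are rated independently by two raters on a four-way category scheme
(personal medication / medication but not personal / irrelevant / non-English)
and, for relevant tweets, on an integer sentiment scale from -5 to 5. Only
tweets on whose category both raters agree are kept. The sentiment measure
Psi over a time window is the plain average of ratings; each rating carries a
unit systematic uncertainty, so the uncertainty on the average of N ratings
is 1/sqrt(N).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Mapping, Optional, Sequence

import math

import pandas as pd

from ._util import bin_index, bin_start
from .types import RaterAnnotation, Tweet

NO_SIDE_EFFECT_TAG = "no side effects"


@dataclass
class ConsensusSet:
    categories: dict[str, int]  # concordant tweet_id -> agreed category
    n_rated: int
    n_concordant: int

    @property
    def agreement_rate(self) -> float:
        return self.n_concordant / self.n_rated if self.n_rated else 0.0

    @property
    def signal_ids(self) -> set[str]:
        return {tid for tid, c in self.categories.items() if c == 1}

    @property
    def noise_ids(self) -> set[str]:
        return {tid for tid, c in self.categories.items() if c in (2, 3)}

    @property
    def non_english_ids(self) -> set[str]:
        """Category-4 tweets, kept aside as a non-English control sample."""
        return {tid for tid, c in self.categories.items() if c == 4}


def consensus(annotations: Iterable[RaterAnnotation]) -> ConsensusSet:
    """Keep tweets whose two raters gave identical category labels.

    Category 1 tweets are the signal class, categories 2-3 the noise class,
    and category 4 the non-English control set. Raises if any tweet was not
    rated by exactly two raters.
    """
    by_tweet: dict[str, list[RaterAnnotation]] = defaultdict(list)
    for a in annotations:
        by_tweet[a.tweet_id].append(a)
    categories: dict[str, int] = {}
    for tid, anns in by_tweet.items():
        if len(anns) != 2:
            raise ValueError(f"tweet {tid!r} has {len(anns)} ratings; exactly 2 required")
        if anns[0].category == anns[1].category:
            categories[tid] = anns[0].category
    return ConsensusSet(categories, n_rated=len(by_tweet), n_concordant=len(categories))


@dataclass
class SentimentSummary:
    psi: Optional[float]
    n: int
    uncertainty: Optional[float]  # 1/sqrt(N)
    window: Optional[tuple[datetime, datetime]] = None


def psi(ratings: Sequence[int]) -> SentimentSummary:
    """Mean sentiment with its 1/sqrt(N) uncertainty. Undefined for no ratings."""
    if len(ratings) == 0:
        raise ValueError("Psi is undefined for an empty rating set")
    for r in ratings:
        if not -5 <= r <= 5:
            raise ValueError(f"rating {r} outside [-5, 5]")
    n = len(ratings)
    return SentimentSummary(psi=sum(ratings) / n, n=n, uncertainty=1.0 / math.sqrt(n))


def sentiment_series(
    rated: Sequence[tuple[datetime, int]],
    bin_days: int = 60,
    origin: Optional[datetime] = None,
) -> list[SentimentSummary]:
    """Psi per half-open time bin [origin + i*W, origin + (i+1)*W).

    A timestamp exactly on a bin boundary belongs to the later bin. Empty
    interior bins are emitted with n=0 and no Psi. `origin` defaults to the
    earliest timestamp.
    """
    if not rated:
        return []
    times = [t for t, _ in rated]
    if origin is None:
        origin = min(times)
    by_bin: dict[int, list[int]] = defaultdict(list)
    for t, r in rated:
        by_bin[bin_index(t, origin, bin_days)].append(r)
    lo, hi = min(by_bin), max(by_bin)
    out = []
    for i in range(lo, hi + 1):
        window = (bin_start(origin, bin_days, i), bin_start(origin, bin_days, i + 1))
        ratings = by_bin.get(i, [])
        if ratings:
            s = psi(ratings)
            out.append(SentimentSummary(s.psi, s.n, s.uncertainty, window))
        else:
            out.append(SentimentSummary(None, 0, None, window))
    return out


@dataclass
class PolaritySummary:
    n_negative: int
    n_neutral: int
    n_positive: int

    @property
    def total(self) -> int:
        return self.n_negative + self.n_neutral + self.n_positive


def polarity(ratings: Iterable[int]) -> PolaritySummary:
    """Counts of strictly negative, zero, and strictly positive ratings."""
    neg = neu = pos = 0
    for r in ratings:
        if r < 0:
            neg += 1
        elif r > 0:
            pos += 1
        else:
            neu += 1
    return PolaritySummary(neg, neu, pos)


def side_effect_summary(
    annotations: Iterable[RaterAnnotation],
    tweets_by_id: Mapping[str, Tweet],
) -> tuple[pd.DataFrame, float]:
    """Drug x side-effect counts over unique users, plus the well-tolerated fraction.

    Retweets are excluded; a user reporting the same (drug, effect) pair in
    several tweets counts once. The second return value is the fraction of
    contributing tweets tagged as reporting no side effects / good tolerance.
    """
    pairs: set[tuple[str, str, str]] = set()  # (user, drug, effect)
    n_tweets = 0
    n_no_effect = 0
    seen_tweets: set[str] = set()
    for a in annotations:
        tweet = tweets_by_id.get(a.tweet_id)
        if tweet is None or tweet.is_retweet:
            continue
        if not a.drugs and not a.side_effects:
            continue
        if a.tweet_id not in seen_tweets:
            seen_tweets.add(a.tweet_id)
            n_tweets += 1
            if NO_SIDE_EFFECT_TAG in a.side_effects:
                n_no_effect += 1
        for drug in a.drugs:
            for effect in a.side_effects:
                if effect == NO_SIDE_EFFECT_TAG:
                    continue
                pairs.add((tweet.user_id, drug, effect))
    if not pairs:
        table = pd.DataFrame()
    else:
        counts: dict[tuple[str, str], int] = defaultdict(int)
        for _, drug, effect in pairs:
            counts[(drug, effect)] += 1
        table = (
            pd.Series(counts).rename_axis(["drug", "side_effect"]).unstack(fill_value=0).sort_index()
        )
    fraction = n_no_effect / n_tweets if n_tweets else 0.0
    return table, fraction
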