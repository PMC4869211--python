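"""Follower-network statistics, demographics, and mention time series.

The identified community is the set of users posting first-person treatment
tweets. Their follow graph (directed: follower -> followee) is induced on
community members; connectivity ("subgraphs of connected components") is
measured on the undirected projection, and reciprocity as per-node mutual
follow counts. Drug-mention and event-substring series use fixed-width
(default 60-day) half-open time bins.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from ._util import bin_index, bin_start, percent
from .filtering import DRUG_KEYWORDS, tokenize
from .types import Tweet, UserProfile

log = logging.getLogger(__name__)

PREP_EVENT_SUBSTRINGS = ("prep", "prevent", "prophy", "approv")


def build_graph(
    users: Sequence[UserProfile],
    edges: Iterable[tuple[str, str]],
    community_ids: Optional[set[str]] = None,
) -> nx.DiGraph:
    """Directed follow graph induced on community members.

    Node attribute ``follower_count`` keeps the platform-wide count from the
    profile. Edges touching unknown users are logged and dropped; self-loops
    are ignored.
    """
    profiles = {u.user_id: u for u in users}
    if community_ids is None:
        community_ids = {u.user_id for u in users if u.in_community}
    g = nx.DiGraph()
    for uid in sorted(community_ids):
        prof = profiles.get(uid)
        g.add_node(uid, follower_count=prof.follower_count if prof else 0)
    n_dropped = 0
    for follower, followee in edges:
        if follower == followee:
            continue
        if follower not in profiles or followee not in profiles:
            n_dropped += 1
            continue
        if follower in community_ids and followee in community_ids:
            g.add_edge(follower, followee)
    if n_dropped:
        log.warning("build_graph: dropped %d edges referencing unknown users", n_dropped)
    return g


@dataclass
class NetworkStats:
    mean_follower_count: float
    within_in_degree: dict[str, int]  # within-community followers per node
    reciprocity: dict[str, int]  # mutual-follow partners per node
    n_components: int  # connected components, undirected projection
    n_undirected_edges: int
    n_directed_edges: int


def network_stats(graph: nx.DiGraph) -> NetworkStats:
    nodes = list(graph.nodes)
    mean_followers = (
        sum(graph.nodes[n].get("follower_count", 0) for n in nodes) / len(nodes) if nodes else 0.0
    )
    in_degree = {n: graph.in_degree(n) for n in nodes}
    reciprocity = {
        n: sum(1 for m in graph.successors(n) if graph.has_edge(m, n)) for n in nodes
    }
    und = graph.to_undirected()
    return NetworkStats(
        mean_follower_count=mean_followers,
        within_in_degree=in_degree,
        reciprocity=reciprocity,
        n_components=nx.number_connected_components(und) if nodes else 0,
        n_undirected_edges=und.number_of_edges(),
        n_directed_edges=graph.number_of_edges(),
    )


def demographics(users: Sequence[UserProfile]) -> dict[str, dict[str, tuple[int, float]]]:
    """Per-category counts and one-decimal percentages for gender and location."""
    out: dict[str, dict[str, tuple[int, float]]] = {}
    if not users:
        return {"gender": {}, "location": {}}
    n = len(users)
    for field_name in ("gender", "location"):
        counts: dict[str, int] = defaultdict(int)
        for u in users:
            value = getattr(u, field_name) or "unknown"
            counts[value] += 1
        out[field_name] = {k: (c, percent(c, n)) for k, c in sorted(counts.items())}
    return out


@dataclass
class MentionSeries:
    bin_starts: list[datetime]
    counts: pd.DataFrame  # index: bin start, columns: top-k drugs + "Other"
    totals: pd.Series  # total mentions per drug, all bins


def _bin_range(tweets: Sequence[Tweet], origin: Optional[datetime], bin_days: int):
    if origin is None:
        origin = min(t.created_at for t in tweets)
    indices = [bin_index(t.created_at, origin, bin_days) for t in tweets]
    return origin, indices, min(indices), max(indices)


def mention_series(
    tweets: Sequence[Tweet],
    drugs: Sequence[str] = DRUG_KEYWORDS,
    bin_days: int = 60,
    top_k: int = 7,
    origin: Optional[datetime] = None,
) -> MentionSeries:
    """Per-bin counts of tweets mentioning each drug (token match).

    Drugs are ranked by total mentions; those outside the top_k are pooled
    under "Other". A tweet naming two drugs counts once toward each.
    """
    if not tweets:
        return MentionSeries([], pd.DataFrame(), pd.Series(dtype=int))
    origin, indices, lo, hi = _bin_range(tweets, origin, bin_days)
    drug_tokens = {d.lower(): d for d in drugs}
    per_drug: dict[str, dict[int, int]] = {d: defaultdict(int) for d in drugs}
    for t, idx in zip(tweets, indices):
        toks = tokenize(t.text)
        for tok in toks & drug_tokens.keys():
            per_drug[drug_tokens[tok]][idx] += 1
    totals = pd.Series({d: sum(bins.values()) for d, bins in per_drug.items()}).sort_values(
        ascending=False, kind="stable"
    )
    named = [d for d in totals.index[:top_k] if totals[d] > 0]
    starts = [bin_start(origin, bin_days, i) for i in range(lo, hi + 1)]
    data = {}
    for d in named:
        data[d] = [per_drug[d].get(i, 0) for i in range(lo, hi + 1)]
    other = [0] * (hi - lo + 1)
    for d in totals.index:
        if d not in named:
            for j, i in enumerate(range(lo, hi + 1)):
                other[j] += per_drug[d].get(i, 0)
    data["Other"] = other
    return MentionSeries(starts, pd.DataFrame(data, index=starts), totals)


def substring_series(
    tweets: Sequence[Tweet],
    substrings: Sequence[str] = PREP_EVENT_SUBSTRINGS,
    bin_days: int = 60,
    origin: Optional[datetime] = None,
) -> pd.DataFrame:
    """Per-bin raw substring occurrence counts (case-insensitive, not tokens).

    Substring semantics are deliberate: "prep" must hit both "PrEP" and
    "preparation".
    """
    if not tweets:
        return pd.DataFrame(columns=list(substrings))
    origin, indices, lo, hi = _bin_range(tweets, origin, bin_days)
    counts = {s: defaultdict(int) for s in substrings}
    for t, idx in zip(tweets, indices):
        text = t.text.lower()
        for s in substrings:
            counts[s][idx] += text.count(s.lower())
    starts = [bin_start(origin, bin_days, i) for i in range(lo, hi + 1)]
    return pd.DataFrame(
        {s: [counts[s].get(i, 0) for i in range(lo, hi + 1)] for s in substrings}, index=starts
    )
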