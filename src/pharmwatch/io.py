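"""Readers and writers for the pipeline's on-disk formats.

Corpora are JSONL (one tweet per line, streamable at tens-of-millions scale);
annotations are CSV with one row per (tweet, rater); follower networks are
whitespace-delimited directed edge lists (``follower followee``); user tables
are CSV. Malformed records fail loudly with the offending line number unless
``skip_bad_lines`` is set, in which case skipped lines are counted and logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._util import ensure_utc, parse_iso
from .types import RaterAnnotation, Tweet, UserProfile

log = logging.getLogger(__name__)

_REQUIRED_TWEET_FIELDS = ("tweet_id", "text", "created_at", "user_id")


class CorpusFormatError(ValueError):
    """A corpus file violated the format contract (bad line, duplicate id...)."""


def read_corpus(path: str | Path, skip_bad_lines: bool = False) -> list[Tweet]:
    path = Path(path)
    tweets: list[Tweet] = []
    seen: set[str] = set()
    n_skipped = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                for f in _REQUIRED_TWEET_FIELDS:
                    if f not in rec:
                        raise CorpusFormatError(f"missing required field {f!r}")
                tweet = Tweet(
                    tweet_id=str(rec["tweet_id"]),
                    text=rec["text"],
                    created_at=parse_iso(rec["created_at"]),
                    user_id=str(rec["user_id"]),
                    truth_class=rec.get("truth_class"),
                    is_retweet=bool(rec.get("is_retweet", False)),
                )
            except (ValueError, TypeError, KeyError) as exc:
                if skip_bad_lines:
                    n_skipped += 1
                    continue
                raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
            if tweet.tweet_id in seen:
                raise CorpusFormatError(f"{path}:{lineno}: duplicate tweet_id {tweet.tweet_id!r}")
            seen.add(tweet.tweet_id)
            tweets.append(tweet)
    if n_skipped:
        log.warning("read_corpus(%s): skipped %d malformed lines", path, n_skipped)
    return tweets


def write_corpus(tweets: Iterable[Tweet], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for t in tweets:
            rec = {
                "tweet_id": t.tweet_id,
                "text": t.text,
                "created_at": ensure_utc(t.created_at).isoformat(),
                "user_id": t.user_id,
            }
            if t.truth_class is not None:
                rec["truth_class"] = t.truth_class
            if t.is_retweet:
                rec["is_retweet"] = True
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


_LIST_SEP = ";"


def read_annotations(path: str | Path) -> list[RaterAnnotation]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"tweet_id", "rater_id", "category"}
    missing = required - set(df.columns)
    if missing:
        raise CorpusFormatError(f"{path}: missing annotation columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        sentiment = getattr(row, "sentiment", "")
        out.append(
            RaterAnnotation(
                tweet_id=row.tweet_id,
                rater_id=row.rater_id,
                category=int(row.category),
                sentiment=int(sentiment) if sentiment != "" else None,
                side_effects=[s for s in getattr(row, "side_effects", "").split(_LIST_SEP) if s],
                drugs=[s for s in getattr(row, "drugs", "").split(_LIST_SEP) if s],
            )
        )
    return out


def write_annotations(annotations: Iterable[RaterAnnotation], path: str | Path) -> None:
    rows = [
        {
            "tweet_id": a.tweet_id,
            "rater_id": a.rater_id,
            "category": a.category,
            "sentiment": "" if a.sentiment is None else a.sentiment,
            "side_effects": _LIST_SEP.join(a.side_effects),
            "drugs": _LIST_SEP.join(a.drugs),
        }
        for a in annotations
    ]
    pd.DataFrame(
        rows, columns=["tweet_id", "rater_id", "category", "sentiment", "side_effects", "drugs"]
    ).to_csv(path, index=False)


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    edges = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise CorpusFormatError(f"{path}:{lineno}: expected 'follower followee'")
            edges.append((parts[0], parts[1]))
    return edges


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for a, b in edges:
            fh.write(f"{a} {b}\n")


def read_users(path: str | Path) -> list[UserProfile]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        UserProfile(
            user_id=row.user_id,
            follower_count=int(row.follower_count),
            gender=row.gender or "unidentified",
            location=row.location or None,
            in_community=row.in_community.lower() == "true",
        )
        for row in df.itertuples(index=False)
    ]


def write_users(users: Sequence[UserProfile], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "user_id": u.user_id,
                "follower_count": u.follower_count,
                "gender": u.gender,
                "location": u.location or "",
                "in_community": u.in_community,
            }
            for u in users
        ],
        columns=["user_id", "follower_count", "gender", "location", "in_community"],
    ).to_csv(path, index=False)
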