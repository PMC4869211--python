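"""Shared data model for the pipeline.

A corpus is a sequence of :class:`Tweet` records; human (or simulated) labels
arrive as :class:`RaterAnnotation` rows, one per (tweet, rater); the follower
graph is a directed edge list over :class:`UserProfile` ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

TRUTH_CLASSES = ("signal", "noise", "foreign")
GENDERS = ("male", "female", "unidentified")

#: annotation categories: 1 = personal medication experience, 2 = medication but
#: not personal, 3 = irrelevant, 4 = not in English
CATEGORIES = (1, 2, 3, 4)


@dataclass
class Tweet:
    tweet_id: str
    text: str
    created_at: datetime
    user_id: str
    truth_class: Optional[str] = None  # synthetic corpora only
    is_retweet: bool = False

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"tweet {self.tweet_id!r}: text must be non-empty")
        if self.truth_class is not None and self.truth_class not in TRUTH_CLASSES:
            raise ValueError(f"tweet {self.tweet_id!r}: bad truth_class {self.truth_class!r}")


@dataclass
class UserProfile:
    user_id: str
    follower_count: int
    gender: str = "unidentified"
    location: Optional[str] = None
    in_community: bool = False

    def __post_init__(self) -> None:
        if self.follower_count < 0:
            raise ValueError(f"user {self.user_id!r}: follower_count must be >= 0")
        if self.gender not in GENDERS:
            raise ValueError(f"user {self.user_id!r}: bad gender {self.gender!r}")


@dataclass
class RaterAnnotation:
    tweet_id: str
    rater_id: str
    category: int
    sentiment: Optional[int] = None
    side_effects: list[str] = field(default_factory=list)
    drugs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"annotation for {self.tweet_id!r}: category must be in 1..4")
        if self.sentiment is not None:
            if not isinstance(self.sentiment, int) or not -5 <= self.sentiment <= 5:
                raise ValueError(
                    f"annotation for {self.tweet_id!r}: sentiment must be an integer in [-5, 5]"
                )
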