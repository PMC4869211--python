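"""Tokenization, keyword inclusion, and the exclusion-filter cascade.

The stream is keyword-matched (antiretroviral brand names plus a few HIV
treatment phrases), then cleaned by three consecutive exclusion stages that
remove link/news/retail and foreign-language tweets before classification:

  stage 1: tweets containing the link tokens ``t.co`` / ``bit.ly``, or whose
           text starts with "HIV" (objective news-style tweets);
  stage 2: tweets containing the tokens ``http``, ``news`` or ``buy``;
  stage 3: tweets containing any of a larger set of retail/news/foreign tokens.

Each stage is a union of :class:`ExclusionRule`s and emits a
:class:`FilterReport` so the per-stage surviving counts can be audited.
Matching is case-insensitive throughout, and stage tokens match as whole
tokens, never substrings ("denied" must not match "de").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .types import Tweet

#: inclusion keywords: 24 antiretroviral brand names + 5 treatment phrases.
KEYWORDS: tuple[str, ...] = (
    "Sustiva", "Stocrin", "Viread", "FTC", "Ziagen", "3TC", "Epivir",
    "Retrovir", "Viramune", "Edurant", "Prezista", "Reyataz", "Norvir",
    "Kaletra", "Isentress", "Tivicay", "Atripla", "Trizivir", "Truvada",
    "Combivir", "Kivexa", "Epzicom", "Complera", "Stribild",
    "HIV treatment", "HIV drug", "anti-HIV", "triple therapy HIV", "anti HIV",
)

#: the single-token drug brand names (used for mention trends).
DRUG_KEYWORDS: tuple[str, ...] = KEYWORDS[:24]

#: tokens drawn from foreign-language dictionaries, seen in the contaminating
#: non-English component of the stream.
FOREIGN_TOKENS: tuple[str, ...] = (
    "de", "e", "za", "que", "en", "lek", "la", "obat", "da",
    "majka", "molim", "hitno", "mil",
)

STAGE3_TOKENS: tuple[str, ...] = ("free", "buy") + FOREIGN_TOKENS + ("africa",)

# Tokens are runs of word characters, keeping internal dots, hyphens and
# apostrophes so "t.co", "bit.ly" and "anti-hiv" survive as single tokens.
# '#'/'@' are not word characters, so hashtag/mention markers fall away.
_TOKEN_RE = re.compile(r"[a-z0-9_]+(?:[.\-'][a-z0-9_]+)*")


def tokenize_ordered(text: str) -> list[str]:
    """Case-folded tokens of `text` in order of appearance (with repeats)."""
    return _TOKEN_RE.findall(text.lower())


def tokenize(text: str) -> set[str]:
    """The set of distinct case-folded tokens the tweet contains."""
    return set(tokenize_ordered(text))


def _keyword_tokens(keyword: str) -> list[str]:
    return tokenize_ordered(keyword)


def match_keywords(tokens: Sequence[str] | set[str], keywords: Sequence[str] = KEYWORDS) -> list[str]:
    """Keywords present in a tweet's tokens.

    Single-token keywords match by membership. Multi-word keywords match when
    their constituent tokens appear consecutively, which requires `tokens` to
    be an *ordered* sequence (from :func:`tokenize_ordered`); if an unordered
    set is supplied, multi-word keywords fall back to all-tokens-present.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    ordered = list(tokens) if not isinstance(tokens, (set, frozenset)) else None
    token_set = set(tokens)
    matched = []
    for kw in keywords:
        parts = _keyword_tokens(kw)
        if len(parts) == 1:
            if parts[0] in token_set:
                matched.append(kw)
        elif ordered is None:
            if all(p in token_set for p in parts):
                matched.append(kw)
        else:
            n = len(parts)
            if any(ordered[i : i + n] == parts for i in range(len(ordered) - n + 1)):
                matched.append(kw)
    return matched


def drop_ftc_subsample(tweets: Iterable[Tweet], keywords: Sequence[str] = KEYWORDS) -> list[Tweet]:
    """Remove tweets whose *only* keyword match is "FTC".

    The FTC brand abbreviation collides with the Federal Trade Commission,
    whose subsample is overwhelmingly commerce/regulation noise. Tweets that
    additionally match another keyword are retained.
    """
    kept = []
    for t in tweets:
        matches = match_keywords(tokenize_ordered(t.text), keywords)
        if matches == ["FTC"]:
            continue
        kept.append(t)
    return kept


@dataclass(frozen=True)
class ExclusionRule:
    mode: str  # contains_token | starts_with | contains_substring
    pattern: str
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("exclusion pattern must be non-empty")
        if self.mode not in ("contains_token", "starts_with", "contains_substring"):
            raise ValueError(f"unknown exclusion mode {self.mode!r}")

    def matches(self, tweet: Tweet, token_set: set[str] | None = None) -> bool:
        text = tweet.text if self.case_sensitive else tweet.text.lower()
        pattern = self.pattern if self.case_sensitive else self.pattern.lower()
        if self.mode == "contains_token":
            tokens = token_set if token_set is not None else tokenize(tweet.text)
            return pattern in tokens
        if self.mode == "starts_with":
            return text.lstrip().startswith(pattern)
        return pattern in text

    @property
    def name(self) -> str:
        return f"{self.mode}:{self.pattern}"


STAGE1_RULES: tuple[ExclusionRule, ...] = (
    ExclusionRule("contains_token", "t.co"),
    ExclusionRule("contains_token", "bit.ly"),
    ExclusionRule("starts_with", "HIV"),
)

STAGE2_RULES: tuple[ExclusionRule, ...] = tuple(
    ExclusionRule("contains_token", p) for p in ("http", "news", "buy")
)

STAGE3_RULES: tuple[ExclusionRule, ...] = tuple(
    ExclusionRule("contains_token", p) for p in STAGE3_TOKENS
)

DEFAULT_STAGES: tuple[tuple[ExclusionRule, ...], ...] = (
    STAGE1_RULES,
    STAGE2_RULES,
    STAGE3_RULES,
)

STAGE_NAMES = ("links-and-hiv-prefix", "http-news-buy", "retail-foreign-tokens")


@dataclass
class FilterReport:
    stage: str
    n_input: int
    n_surviving: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_surviving > self.n_input:
            raise ValueError("surviving count exceeds input count")


def apply_stage(
    tweets: Sequence[Tweet], rules: Sequence[ExclusionRule], name: str = "stage"
) -> tuple[list[Tweet], FilterReport]:
    """Remove tweets matching any rule in `rules` (rules are unioned)."""
    removed_by_rule = {r.name: 0 for r in rules}
    survivors = []
    for t in tweets:
        token_set = tokenize(t.text)
        hit = False
        for r in rules:
            if r.matches(t, token_set):
                removed_by_rule[r.name] += 1
                hit = True
        if not hit:
            survivors.append(t)
    return survivors, FilterReport(name, len(tweets), len(survivors), removed_by_rule)


def apply_cascade(
    tweets: Sequence[Tweet],
    stages: Sequence[Sequence[ExclusionRule]] = DEFAULT_STAGES,
    stage_names: Sequence[str] | None = None,
) -> tuple[list[Tweet], list[FilterReport]]:
    """Apply the ordered exclusion stages, emitting one report per stage."""
    names = list(stage_names) if stage_names is not None else [
        STAGE_NAMES[i] if i < len(STAGE_NAMES) else f"stage-{i + 1}" for i in range(len(stages))
    ]
    reports = []
    current = list(tweets)
    for rules, name in zip(stages, names):
        current, report = apply_stage(current, rules, name)
        reports.append(report)
    return current, reports


#: English function words (closed-class: articles, pronouns, prepositions,
#: auxiliaries, conjunctions, common adverbs, plus clitic fragments left by
#: apostrophe-free tweet spelling: "i m", "it s", "don t").
ENGLISH_FUNCTION_WORDS: frozenset[str] = frozenset("""
a an the and or but if so as of at by for with about against between into
through during before after above below to from in on up down out off over
under again further then once here there when where why how all any both each
few more most other some such no not nor only own same than too very just
i me my mine myself we us our ours you your yours he him his she her hers it
its they them their theirs this that these those who whom which what
am is are was were be been being have has had having do does did doing
can could will would shall should may might must
m s re ve ll d t don didn isn aren wasn won
like also still already yet ever never now today get got go going went come
oh ok okay well really
""".split())


class EnglishDetector:
    """Scores how English a tweet looks: the fraction of its tokens that are
    closed-class English function words. Foreign-token salads score ~0.
    """

    def __init__(
        self,
        function_words: frozenset[str] = ENGLISH_FUNCTION_WORDS,
        threshold: float = 0.15,
    ) -> None:
        if not function_words:
            raise ValueError("detector needs a non-empty function-word set")
        if not 0 < threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        self.function_words = function_words
        self.threshold = threshold

    def score(self, text: str) -> float:
        tokens = tokenize_ordered(text)
        if not tokens:
            return 0.0
        return sum(tok in self.function_words for tok in tokens) / len(tokens)

    def is_english(self, text: str) -> bool:
        return self.score(text) >= self.threshold


def remove_non_english(tweets: Iterable[Tweet], detector: EnglishDetector) -> list[Tweet]:
    """Drop tweets scoring below the detector's English threshold."""
    if detector is None:
        raise ValueError("English detector is required")
    return [t for t in tweets if detector.is_english(t.text)]
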