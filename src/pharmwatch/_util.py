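"""Small shared helpers: rounding, time binning, seed fan-out."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone
from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def percent(numerator: int | float, denominator: int | float, decimals: int = 1) -> float:
    """Percentage rounded half-up to `decimals`, matching tabular reporting style.

    Uses exact decimal arithmetic so 35.55 rounds to 35.6, not 35.5.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty set is undefined")
    q = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    step = Decimal(1).scaleb(-decimals)
    return float(q.quantize(step, rounding=ROUND_HALF_UP))


def ensure_utc(t: datetime) -> datetime:
    if t.tzinfo is None:
        return t.replace(tzinfo=timezone.utc)
    return t.astimezone(timezone.utc)


def parse_iso(value: str) -> datetime:
    return ensure_utc(datetime.fromisoformat(value))


def bin_index(t: datetime, origin: datetime, bin_days: int) -> int:
    """Index of the half-open bin [origin + i*W, origin + (i+1)*W) containing t."""
    delta = ensure_utc(t) - ensure_utc(origin)
    width = timedelta(days=bin_days)
    # floor division on timedeltas handles negative offsets correctly
    return delta // width


def bin_start(origin: datetime, bin_days: int, index: int) -> datetime:
    return ensure_utc(origin) + timedelta(days=bin_days) * index


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fan a single seed out into n independent generators, one per stage."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
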