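"""Small shared helpers: reporting-grade rounding and date/day arithmetic."""

from __future__ import annotations

import decimal

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), as used in published tables.

    Python's built-in ``round`` is banker's rounding; report tables round
    97.5 -> 98, so we go through :mod:`decimal`.
    """
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up; raises on a zero denominator."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def to_day(dates, origin) -> np.ndarray:
    """Convert datetime-like values to integer day offsets from ``origin``."""
    dates = pd.to_datetime(pd.Series(dates) if not isinstance(dates, pd.Series) else dates)
    origin = pd.Timestamp(origin)
    return ((dates - origin) // pd.Timedelta(days=1)).to_numpy()


def from_day(days, origin) -> pd.Series:
    origin = pd.Timestamp(origin)
    return pd.Series(pd.to_datetime(origin) + pd.to_timedelta(np.asarray(days), unit="D"))
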