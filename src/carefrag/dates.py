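"""Calendar-date arithmetic conventions used throughout the package.

All intervals ("within 6 months", ">= 3 months apart", "within 2 years")
use calendar arithmetic — same day-of-month, clamped to month end — with
inclusive boundaries. Dates are calendar dates; no times, no time zones.
"""

from __future__ import annotations

import pandas as pd


def add_months(date, n: int) -> pd.Timestamp:
    return pd.Timestamp(date) + pd.DateOffset(months=n)


def add_years(date, n: int) -> pd.Timestamp:
    return pd.Timestamp(date) + pd.DateOffset(years=n)


def within_months(d1, d2, n: int) -> bool:
    """True iff the two dates are at most n calendar months apart (inclusive)."""
    lo, hi = sorted([pd.Timestamp(d1), pd.Timestamp(d2)])
    return hi <= add_months(lo, n)


def within_years(d1, d2, n: int) -> bool:
    lo, hi = sorted([pd.Timestamp(d1), pd.Timestamp(d2)])
    return hi <= add_years(lo, n)


def months_apart_at_least(d1, d2, n: int) -> bool:
    """True iff the two dates are at least n calendar months apart (inclusive)."""
    lo, hi = sorted([pd.Timestamp(d1), pd.Timestamp(d2)])
    return hi >= add_months(lo, n)


def age_at(birth_date, reference_date) -> int:
    """Age in completed years at the reference date."""
    birth = pd.Timestamp(birth_date)
    ref = pd.Timestamp(reference_date)
    years = ref.year - birth.year
    if (ref.month, ref.day) < (birth.month, birth.day):
        years -= 1
    return years
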