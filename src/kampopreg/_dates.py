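"""Month-granular calendar helpers.

The claims source exposes enrollment and birth information at year-month
granularity only, so several pipeline rules (coverage continuity, the
delivery-date fallback, the infant follow-up window) operate on "YYYY-MM"
strings. These helpers centralise the conversions.
"""
from __future__ import annotations

import datetime as dt

import pandas as pd


def ym(d: dt.date | pd.Timestamp) -> str:
    """Year-month string for a calendar date."""
    return f"{d.year:04d}-{d.month:02d}"


def month_start(yearmonth: str) -> dt.date:
    p = pd.Period(yearmonth, freq="M")
    return dt.date(p.year, p.month, 1)


def month_end(yearmonth: str) -> dt.date:
    p = pd.Period(yearmonth, freq="M")
    return p.to_timestamp(how="end").date()


def month_mid(yearmonth: str) -> dt.date:
    """The 15th of the month — the dating fallback convention."""
    p = pd.Period(yearmonth, freq="M")
    return dt.date(p.year, p.month, 15)


def add_months(yearmonth: str, k: int) -> str:
    p = pd.Period(yearmonth, freq="M") + k
    return str(p)


def months_between(a: str, b: str) -> int:
    """Whole months from year-month ``a`` to ``b`` (b - a)."""
    return (pd.Period(b, freq="M") - pd.Period(a, freq="M")).n
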