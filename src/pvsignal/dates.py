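"""Partial calendar dates as they occur in spontaneous-report databases.

FAERS date fields are ``yyyymmdd`` strings that are frequently truncated to
``yyyymm`` or ``yyyy`` or empty. Rather than coercing these to a full date
(which would invent information), a :class:`PartialDate` carries an explicit
precision tag and downstream operations declare the precision they require:
deduplication orders on whatever precision is available, while time-to-onset
requires day precision on both endpoints.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from enum import Enum
from typing import Optional


class DatePrecision(str, Enum):
    DAY = "day"
    MONTH = "month"
    YEAR = "year"


@dataclass(frozen=True, order=False)
class PartialDate:
    """A calendar date known to day, month or year precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    @property
    def precision(self) -> DatePrecision:
        if self.day is not None:
            return DatePrecision.DAY
        if self.month is not None:
            return DatePrecision.MONTH
        return DatePrecision.YEAR

    def to_date(self) -> _dt.date:
        """Full date; only valid at day precision."""
        if self.precision is not DatePrecision.DAY:
            raise ValueError(f"date {self} has {self.precision.value} precision, not day")
        return _dt.date(self.year, self.month, self.day)  # type: ignore[arg-type]

    def sort_key(self) -> str:
        """Zero-padded string ordering key; unknown components sort first.

        ``"2020" < "202001" < "20200101"`` under plain string comparison, so
        a coarser date never outranks a finer date in the same period.
        """
        s = f"{self.year:04d}"
        if self.month is not None:
            s += f"{self.month:02d}"
            if self.day is not None:
                s += f"{self.day:02d}"
        return s

    def __str__(self) -> str:
        return self.sort_key()


def parse_partial_date(raw: object) -> Optional[PartialDate]:
    """Parse a FAERS-style date string (yyyymmdd / yyyymm / yyyy).

    Empty strings, None/NaN and malformed values parse to ``None`` (missing);
    parsing is total and never raises on data.
    """
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.lower() in {"nan", "<na>", "none"}:
        return None
    if not s.isdigit():
        return None
    try:
        if len(s) == 4:
            return PartialDate(int(s))
        if len(s) == 6:
            pd_ = PartialDate(int(s[:4]), int(s[4:6]))
            _dt.date(pd_.year, pd_.month, 1)
            return pd_
        if len(s) == 8:
            pd_ = PartialDate(int(s[:4]), int(s[4:6]), int(s[6:8]))
            pd_.to_date()
            return pd_
    except ValueError:
        return None
    return None


def date_sort_key(raw: object) -> str:
    """Ordering key for a raw date field; missing/unparseable sorts minimal."""
    pd_ = parse_partial_date(raw)
    return "" if pd_ is None else pd_.sort_key()


def days_between(start: PartialDate, end: PartialDate) -> Optional[int]:
    """Day difference end − start; None unless both have day precision."""
    if start.precision is not DatePrecision.DAY or end.precision is not DatePrecision.DAY:
        return None
    return (end.to_date() - start.to_date()).days
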