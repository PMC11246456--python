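"""Partial-precision date handling for FAERS date fields.

FAERS dates are numeric strings of 4 (YYYY), 6 (YYYYMM) or 8 (YYYYMMDD)
digits; any of the three may appear in the same column.  Day-level
arithmetic (time-to-onset, date-error filtering) is only meaningful when
both operands are full precision, so the parsed value carries an explicit
precision tag instead of being silently padded.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class PartialDate:
    """A calendar date known to year, month or day precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    @property
    def is_full(self) -> bool:
        return self.day is not None

    def to_date(self) -> _dt.date:
        """Full-precision dates only; raises otherwise."""
        if not self.is_full:
            raise ValueError(f"date {self} has {self.precision} precision")
        return _dt.date(self.year, self.month, self.day)

    def isoformat(self) -> str:
        if self.precision == "day":
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.precision == "month":
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"

    def sort_key(self) -> tuple:
        # Missing components sort before any real value, so a YYYYMM date
        # never outranks a YYYYMMDD date in the same month.
        return (self.year, self.month or 0, self.day or 0)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()


def parse_faers_date(raw: object) -> Optional[PartialDate]:
    """Parse a FAERS date string; return None when missing or malformed.

    Accepts YYYYMMDD, YYYYMM and YYYY.  A value whose components do not
    form a real calendar date (e.g. month 13, Feb 30) is treated as
    malformed and returns None — callers decide whether to warn.
    """
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.lower() in {"nan", "none"}:
        return None
    if not s.isdigit():
        return None
    if len(s) == 8:
        y, m, d = int(s[:4]), int(s[4:6]), int(s[6:8])
        try:
            _dt.date(y, m, d)
        except ValueError:
            return None
        return PartialDate(y, m, d)
    if len(s) == 6:
        y, m = int(s[:4]), int(s[4:6])
        if not 1 <= m <= 12:
            return None
        return PartialDate(y, m)
    if len(s) == 4:
        y = int(s)
        if y < 1900 or y > 2100:
            return None
        return PartialDate(y)
    return None


def days_between(start: PartialDate, end: PartialDate) -> int:
    """Whole days from *start* to *end*; both must be full precision."""
    return (end.to_date() - start.to_date()).days
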