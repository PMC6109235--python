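"""Calendar-month arithmetic.

Everything in the pipeline — scanner aggregates, CPI deflators, tax
policy changes, budget cycles — is resolved to the calendar month.
Budget enactments that fall mid-month (UK budgets land on the
18th–24th) are attributed to the month containing them.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering

_MONTH_RE = re.compile(r"^(\d{4})-(\d{1,2})$")


@total_ordering
@dataclass(frozen=True)
class Month:
    """A calendar month, ordered and hashable.

    Supports ``month + n`` (months), ``month - month`` (signed month
    count) and parsing/formatting of the ``YYYY-MM`` form used in all
    CSV and YAML interfaces.
    """

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")

    @property
    def ordinal(self) -> int:
        """Months since year 0, a convenient integer sort key."""
        return self.year * 12 + self.month - 1

    @classmethod
    def from_ordinal(cls, ordinal: int) -> "Month":
        return cls(ordinal // 12, ordinal % 12 + 1)

    @classmethod
    def parse(cls, text: "str | Month") -> "Month":
        if isinstance(text, Month):
            return text
        m = _MONTH_RE.match(str(text).strip())
        if m is None:
            raise ValueError(f"expected YYYY-MM, got {text!r}")
        return cls(int(m.group(1)), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"

    def __lt__(self, other: object) -> bool:
        if not isinstance(other, Month):
            return NotImplemented
        return self.ordinal < other.ordinal

    def __add__(self, n: int) -> "Month":
        if not isinstance(n, int):
            return NotImplemented
        return Month.from_ordinal(self.ordinal + n)

    def __sub__(self, other: "Month | int"):
        if isinstance(other, Month):
            return self.ordinal - other.ordinal
        if isinstance(other, int):
            return Month.from_ordinal(self.ordinal - other)
        return NotImplemented


def month_range(start: Month, end: Month) -> list[Month]:
    """Inclusive list of months from *start* to *end*."""
    if end < start:
        raise ValueError(f"end {end} precedes start {start}")
    return [Month.from_ordinal(o) for o in range(start.ordinal, end.ordinal + 1)]
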