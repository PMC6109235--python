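"""Exception hierarchy shared across the package."""
from __future__ import annotations


class TaxShiftError(Exception):
    """Base class for all package errors."""


class PanelFormatError(TaxShiftError):
    """Structural problem in a panel CSV (missing column, bad header)."""


class RowInvariantError(TaxShiftError):
    """One or more rows of a panel CSV violate record invariants.

    Carries ``problems``: a list of ``(row_number, message)`` pairs,
    1-based counting the header as row 1.
    """

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = list(problems)
        lines = "; ".join(f"row {r}: {msg}" for r, msg in self.problems[:20])
        extra = "" if len(self.problems) <= 20 else f" (+{len(self.problems) - 20} more)"
        super().__init__(f"{len(self.problems)} invalid row(s): {lines}{extra}")


class UndefinedPriceError(TaxShiftError):
    """Unit price requested for a record with zero units sold."""


class MissingDeflatorError(TaxShiftError):
    """CPI index has no entry for the requested month."""


class NoPolicyError(TaxShiftError):
    """Tax policy requested for a month before the timeline starts."""


class UndefinedMetricError(TaxShiftError):
    """A metric is undefined for the given slice (empty, or data not yet
    collected in that month, e.g. price-marking before its availability
    date)."""


class ScenarioError(TaxShiftError):
    """Synthetic market scenario is invalid or not covered by the
    supplied tax timeline / CPI series."""
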