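"""Scanner-panel data model, CSV dialect and price plumbing.

The unit of observation is one SKU (stock keeping unit — a single
barcode: brand variant x pack size x pack features) in one calendar
month, carrying the total sales value and the number of packs sold.
The unit pack price is always derived as sales_value / units_sold so
that value, volume and price are internally consistent by construction.

Money is held in integer pence internally and rendered as GBP at the
edges; this keeps accounting identities exact and testable.

Panel CSV dialect (header order is fixed)::

    sku_id,brand_family,brand_variant,product_type,pack_size,multipack,
    price_marked,month,sales_value_gbp,units_sold

``product_type`` is ``FM`` (factory-made cigarettes, pack_size in
sticks) or ``RYO`` (roll-your-own tobacco, pack_size in grams).
``price_marked`` is tri-state: ``true`` / ``false`` / empty (unknown —
the flag only exists in the source data from a configurable
availability month). ``month`` is ``YYYY-MM``.

CPI CSV dialect: ``month,index``.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    MissingDeflatorError,
    PanelFormatError,
    RowInvariantError,
    UndefinedPriceError,
)
from .months import Month

__all__ = [
    "FM",
    "RYO",
    "PRODUCT_TYPES",
    "PM_AVAILABLE_FROM",
    "SkuMonthRecord",
    "StickEquivalence",
    "CpiSeries",
    "unit_price",
    "unit_price_pence",
    "to_real",
    "sticks_per_pack",
    "read_panel",
    "read_panel_audited",
    "write_panel",
    "read_cpi",
    "write_cpi",
    "panel_frame",
]

FM = "FM"
RYO = "RYO"
PRODUCT_TYPES = (FM, RYO)

#: Month from which the price-marked flag exists in the source data.
PM_AVAILABLE_FROM = Month(2011, 8)

PANEL_COLUMNS = [
    "sku_id",
    "brand_family",
    "brand_variant",
    "product_type",
    "pack_size",
    "multipack",
    "price_marked",
    "month",
    "sales_value_gbp",
    "units_sold",
]


@dataclass(frozen=True)
class StickEquivalence:
    """Conversion of loose tobacco weight to cigarette-stick equivalents.

    One RYO stick is taken to contain 0.5 g of tobacco by default (the
    survey-based average weight of a hand-rolled cigarette in the UK),
    so a 12.5 g pouch counts as 25 sticks.
    """

    grams_per_ryo_stick: float = 0.5

    def __post_init__(self) -> None:
        if not self.grams_per_ryo_stick > 0:
            raise ValueError("grams_per_ryo_stick must be positive")


DEFAULT_EQ = StickEquivalence()


@dataclass(frozen=True)
class SkuMonthRecord:
    """One SKU in one month.

    pack_size is sticks for FM and grams for RYO; for multipacks it is
    the total content of the sale unit (duty is per quantity, not per
    wrapper). ``price_marked`` is None when the flag is unknown (before
    its availability date in the source data).
    """

    sku_id: str
    brand_family: str
    brand_variant: str
    product_type: str
    pack_size: float
    multipack: bool
    price_marked: bool | None
    month: Month
    sales_value_pence: int
    units_sold: int

    def __post_init__(self) -> None:
        problems = self.invariant_violations()
        if problems:
            raise ValueError("; ".join(problems))

    def invariant_violations(self) -> list[str]:
        out: list[str] = []
        if self.product_type not in PRODUCT_TYPES:
            out.append(f"product_type must be FM or RYO, got {self.product_type!r}")
        if not self.pack_size > 0 or not math.isfinite(self.pack_size):
            out.append(f"pack_size must be positive, got {self.pack_size}")
        if self.units_sold < 0:
            out.append(f"units_sold must be >= 0, got {self.units_sold}")
        if self.sales_value_pence < 0:
            out.append(f"sales_value must be >= 0, got {self.sales_value_pence}p")
        if self.units_sold > 0 and self.sales_value_pence <= 0:
            out.append("sales_value must be positive when units were sold")
        return out

    @property
    def sales_value_gbp(self) -> float:
        return self.sales_value_pence / 100.0


def unit_price_pence(record: SkuMonthRecord) -> float:
    """Pack price in pence, derived as sales value / packs sold.

    Raises :class:`UndefinedPriceError` when no packs were sold; the
    caller must skip the record, never substitute zero.
    """
    if record.units_sold == 0:
        raise UndefinedPriceError(f"{record.sku_id} {record.month}: no units sold")
    return record.sales_value_pence / record.units_sold


def unit_price(record: SkuMonthRecord) -> float:
    """Pack price in GBP (see :func:`unit_price_pence`)."""
    return unit_price_pence(record) / 100.0


def sticks_per_pack(record: SkuMonthRecord, eq: StickEquivalence = DEFAULT_EQ) -> float:
    """Stick-equivalent content of one sale unit (real-valued for RYO)."""
    if record.product_type == FM:
        return float(record.pack_size)
    return record.pack_size / eq.grams_per_ryo_stick


@dataclass(frozen=True)
class CpiSeries:
    """Monthly consumer price index with a designated base month.

    Real (inflation-adjusted) prices are nominal prices rescaled to
    base-month money: real = nominal * index[base] / index[month].
    Missing months are hard errors — no interpolation, since silently
    filling a deflator would corrupt real-price trends.
    """

    index: Mapping[Month, float]
    base_month: Month

    def __post_init__(self) -> None:
        if self.base_month not in self.index:
            raise ValueError(f"base month {self.base_month} not in CPI series")
        for m, v in self.index.items():
            if not v > 0:
                raise ValueError(f"CPI index must be positive, got {v} at {m}")

    def deflator(self, month: Month) -> float:
        """Multiplier taking nominal money of *month* to base-month money."""
        try:
            return self.index[self.base_month] / self.index[month]
        except KeyError:
            raise MissingDeflatorError(f"no CPI index for {month}") from None

    def to_real(self, nominal: float, month: Month) -> float:
        return nominal * self.deflator(month)

    def __contains__(self, month: Month) -> bool:
        return month in self.index


def to_real(nominal: float, month: Month, cpi: CpiSeries) -> float:
    """Deflate a nominal GBP amount of *month* to base-month terms."""
    return cpi.to_real(nominal, month)


# ---------------------------------------------------------------------------
# CSV readers / writers


def _parse_bool(text: str, column: str, row: int) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValueError(f"row {row}: {column} must be true/false, got {text!r}")


def _parse_row(row: Mapping[str, str], rownum: int) -> SkuMonthRecord:
    try:
        pack_size = float(row["pack_size"])
    except ValueError:
        raise ValueError(f"non-numeric pack_size {row['pack_size']!r}") from None
    try:
        sales_value = float(row["sales_value_gbp"])
    except ValueError:
        raise ValueError(
            f"non-numeric sales_value_gbp {row['sales_value_gbp']!r}"
        ) from None
    try:
        units = int(row["units_sold"])
    except ValueError:
        raise ValueError(f"non-integer units_sold {row['units_sold']!r}") from None

    pm_text = row["price_marked"].strip()
    price_marked = None if pm_text == "" else _parse_bool(pm_text, "price_marked", rownum)

    return SkuMonthRecord(
        sku_id=row["sku_id"],
        brand_family=row["brand_family"],
        brand_variant=row["brand_variant"],
        product_type=row["product_type"].strip(),
        pack_size=pack_size,
        multipack=_parse_bool(row["multipack"], "multipack", rownum),
        price_marked=price_marked,
        month=Month.parse(row["month"]),
        sales_value_pence=round(sales_value * 100),
        units_sold=units,
    )


@dataclass
class PanelReadResult:
    """Accepted records plus row-numbered diagnostics for rejected rows."""

    records: list[SkuMonthRecord]
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.records)


def read_panel_audited(path: str | Path) -> PanelReadResult:
    """Read a panel CSV, collecting (not raising) per-row problems.

    Structural problems — a missing required column — still raise
    :class:`PanelFormatError` immediately.
    """
    path = Path(path)
    result = PanelReadResult(records=[])
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in PANEL_COLUMNS if c not in header]
        if missing:
            raise PanelFormatError(
                f"{path.name}: missing required column(s): {', '.join(missing)}"
            )
        for rownum, row in enumerate(reader, start=2):  # header is row 1
            try:
                result.records.append(_parse_row(row, rownum))
            except (ValueError, KeyError) as exc:
                result.rejected.append((rownum, str(exc)))
    return result


def read_panel(path: str | Path) -> list[SkuMonthRecord]:
    """Read a panel CSV strictly: any invalid row raises
    :class:`RowInvariantError` listing row numbers."""
    result = read_panel_audited(path)
    if result.rejected:
        raise RowInvariantError(result.rejected)
    return result.records


def write_panel(records: Iterable[SkuMonthRecord], path: str | Path) -> None:
    """Write records in the documented panel CSV dialect.

    The dialect round-trips bit-exactly with :func:`read_panel`:
    money is formatted from integer pence with two decimals.
    """
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PANEL_COLUMNS)
        for r in records:
            pm = "" if r.price_marked is None else str(r.price_marked).lower()
            writer.writerow(
                [
                    r.sku_id,
                    r.brand_family,
                    r.brand_variant,
                    r.product_type,
                    f"{r.pack_size:g}",
                    str(r.multipack).lower(),
                    pm,
                    str(r.month),
                    f"{r.sales_value_pence / 100:.2f}",
                    r.units_sold,
                ]
            )


def read_cpi(path: str | Path, base_month: Month | str | None = None) -> CpiSeries:
    """Read a CPI CSV (``month,index``). The base month defaults to the
    first row."""
    index: dict[Month, float] = {}
    first: Month | None = None
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"month", "index"} <= set(reader.fieldnames):
            raise PanelFormatError(f"{Path(path).name}: CPI CSV needs columns month,index")
        for row in reader:
            m = Month.parse(row["month"])
            if first is None:
                first = m
            index[m] = float(row["index"])
    if not index:
        raise PanelFormatError(f"{Path(path).name}: empty CPI series")
    base = first if base_month is None else Month.parse(base_month)
    return CpiSeries(index=index, base_month=base)


def write_cpi(cpi: CpiSeries, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["month", "index"])
        for m in sorted(cpi.index, key=lambda m: m.ordinal):
            writer.writerow([str(m), repr(cpi.index[m])])


# ---------------------------------------------------------------------------
# Tabular view


def panel_frame(
    records: Sequence[SkuMonthRecord],
    cpi: CpiSeries | None = None,
    eq: StickEquivalence = DEFAULT_EQ,
) -> pd.DataFrame:
    """Long DataFrame view of a panel, one row per record.

    Adds derived columns used throughout the metrics layer: stick
    content, total sticks sold, unit pack price and (when a CPI series
    is given) real pack and stick prices. Records with zero units get
    NaN prices rather than zeros.
    """
    rows = []
    for r in records:
        spp = sticks_per_pack(r, eq)
        price = unit_price(r) if r.units_sold > 0 else math.nan
        rows.append(
            {
                "sku_id": r.sku_id,
                "brand_family": r.brand_family,
                "brand_variant": r.brand_variant,
                "product_type": r.product_type,
                "pack_size": r.pack_size,
                "multipack": r.multipack,
                "price_marked": r.price_marked,
                "month": str(r.month),
                "month_ord": r.month.ordinal,
                "year": r.month.year,
                "sticks_per_pack": spp,
                "units": r.units_sold,
                "sticks": r.units_sold * spp,
                "price_gbp": price,
            }
        )
    df = pd.DataFrame(rows)
    if cpi is not None and len(df):
        deflators = {
            o: cpi.deflator(Month.from_ordinal(o)) for o in df["month_ord"].unique()
        }
        df["real_price_gbp"] = df["price_gbp"] * df["month_ord"].map(deflators)
        df["real_stick_price_gbp"] = df["real_price_gbp"] / df["sticks_per_pack"]
    return df
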