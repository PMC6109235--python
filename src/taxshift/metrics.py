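"""Descriptive market metrics on a segmented panel.

All price metrics are volume-weighted real (CPI-deflated) prices:
pack prices weight by packs sold, stick prices weight by sticks sold,
and data on all pack sizes are pooled within a segment. Price metrics
default to single packs only; volume metrics include everything.
Medians over an even count use the midpoint of the two central values.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .market_data import (
    DEFAULT_EQ,
    PM_AVAILABLE_FROM,
    CpiSeries,
    SkuMonthRecord,
    StickEquivalence,
    panel_frame,
)
from .months import Month
from .segmentation import SegmentAssignments
from .tax_engine import PolicyTimeline

__all__ = [
    "weighted_avg_real_price",
    "volumes_by",
    "pack_size_shares",
    "PriceMarkingStats",
    "price_marking_stats",
    "segment_stick_price_series",
    "postbudget_median_rise",
    "segment_month_metrics",
]


def _wavg(values: np.ndarray, weights: np.ndarray) -> float:
    return float(np.average(values, weights=weights))


def _priced(
    records: Sequence[SkuMonthRecord],
    cpi: CpiSeries,
    eq: StickEquivalence,
    single_packs_only: bool,
) -> pd.DataFrame:
    df = panel_frame(records, cpi=cpi, eq=eq)
    if len(df) == 0:
        return df
    df = df[df["units"] > 0]
    if single_packs_only:
        df = df[~df["multipack"]]
    return df


def weighted_avg_real_price(
    records: Sequence[SkuMonthRecord],
    cpi: CpiSeries,
    *,
    eq: StickEquivalence = DEFAULT_EQ,
    basis: str = "pack",
    single_packs_only: bool = True,
) -> float:
    """Volume-weighted average real price of a record slice, in GBP.

    ``basis="pack"``: mean pack price weighted by packs sold, all pack
    sizes pooled. ``basis="stick"``: mean per-stick price weighted by
    sticks sold. Raises :class:`UndefinedMetricError` on a slice with
    no sold units.
    """
    if basis not in ("pack", "stick"):
        raise ValueError(f"basis must be 'pack' or 'stick', got {basis!r}")
    df = _priced(records, cpi, eq, single_packs_only)
    if len(df) == 0:
        raise UndefinedMetricError("no sold units in slice")
    if basis == "pack":
        return _wavg(df["real_price_gbp"].to_numpy(), df["units"].to_numpy())
    return _wavg(df["real_stick_price_gbp"].to_numpy(), df["sticks"].to_numpy())


def volumes_by(
    records: Sequence[SkuMonthRecord],
    by: str = "total",
    assignments: SegmentAssignments | None = None,
    eq: StickEquivalence = DEFAULT_EQ,
) -> pd.DataFrame:
    """Monthly stick-equivalent volumes, grouped.

    ``by`` is ``"total"``, ``"product_type"`` or ``"segment"`` (the
    latter needs *assignments*; unassigned SKU-months are dropped from
    the segment view). Groupings partition the panel, so group sums
    conserve totals.
    """
    df = panel_frame(records, eq=eq)
    if len(df) == 0:
        return pd.DataFrame(columns=["month_ord", "sticks"])
    if by == "total":
        keys = ["month_ord"]
    elif by == "product_type":
        keys = ["month_ord", "product_type"]
    elif by == "segment":
        if assignments is None:
            raise ValueError("by='segment' requires assignments")
        df = df.merge(
            assignments.frame[["sku_id", "month_ord", "segment"]],
            on=["sku_id", "month_ord"],
            how="inner",
        )
        keys = ["month_ord", "product_type", "segment"]
    else:
        raise ValueError(f"unknown grouping {by!r}")
    out = df.groupby(keys, as_index=False)["sticks"].sum()
    out["month"] = out["month_ord"].map(lambda o: str(Month.from_ordinal(o)))
    return out


def pack_size_shares(
    records: Sequence[SkuMonthRecord],
    assignments: SegmentAssignments,
    eq: StickEquivalence = DEFAULT_EQ,
) -> pd.DataFrame:
    """Annual stick-volume share of each pack size within product type
    x segment. Shares sum to 1 within each segment-year."""
    df = panel_frame(records, eq=eq)
    df = df.merge(
        assignments.frame[["sku_id", "month_ord", "segment"]],
        on=["sku_id", "month_ord"],
        how="inner",
    )
    g = df.groupby(["product_type", "segment", "year", "pack_size"], as_index=False)[
        "sticks"
    ].sum()
    totals = g.groupby(["product_type", "segment", "year"])["sticks"].transform("sum")
    g["share"] = g["sticks"] / totals
    return g


@dataclass(frozen=True)
class PriceMarkingStats:
    """Prevalence and price gap of price-marked (PM) packs in a slice.

    ``price_gap_pct`` is the percentage difference between the
    volume-weighted real price of PM and non-PM packs, negative when
    PM packs are cheaper; None when either arm is empty.
    """

    pct_price_marked: float
    price_gap_pct: float | None
    pm_packs: int
    known_packs: int


def price_marking_stats(
    records: Sequence[SkuMonthRecord],
    cpi: CpiSeries,
    month: Month,
    *,
    eq: StickEquivalence = DEFAULT_EQ,
    availability: Month = PM_AVAILABLE_FROM,
    single_packs_only: bool = True,
) -> PriceMarkingStats:
    """Price-marking prevalence and PM/non-PM price gap for one month.

    Months before the flag's availability date raise
    :class:`UndefinedMetricError` (unknown, never zero). Records with
    an unknown flag are excluded from the denominator.
    """
    if month < availability:
        raise UndefinedMetricError(
            f"price-marking unknown before {availability} (asked for {month})"
        )
    df = _priced(records, cpi, eq, single_packs_only)
    df = df[(df["month_ord"] == month.ordinal) & df["price_marked"].notna()]
    if len(df) == 0:
        raise UndefinedMetricError(f"no known-flag records in {month}")
    pm = df[df["price_marked"] == True]  # noqa: E712 (object dtype)
    non = df[df["price_marked"] == False]  # noqa: E712
    pm_packs = int(pm["units"].sum())
    known = int(df["units"].sum())
    gap = None
    if len(pm) and len(non):
        p_pm = _wavg(pm["real_price_gbp"].to_numpy(), pm["units"].to_numpy())
        p_non = _wavg(non["real_price_gbp"].to_numpy(), non["units"].to_numpy())
        gap = (p_pm - p_non) / p_non * 100.0
    return PriceMarkingStats(
        pct_price_marked=pm_packs / known * 100.0,
        price_gap_pct=gap,
        pm_packs=pm_packs,
        known_packs=known,
    )


def segment_stick_price_series(
    records: Sequence[SkuMonthRecord],
    assignments: SegmentAssignments,
    cpi: CpiSeries,
    *,
    eq: StickEquivalence = DEFAULT_EQ,
    single_packs_only: bool = True,
) -> pd.DataFrame:
    """Monthly volume-weighted real stick price per product type x
    segment (long frame: product_type, segment, month_ord,
    stick_price_gbp)."""
    df = _priced(records, cpi, eq, single_packs_only)
    df = df.merge(
        assignments.frame[["sku_id", "month_ord", "segment"]],
        on=["sku_id", "month_ord"],
        how="inner",
    )
    df["pw"] = df["real_stick_price_gbp"] * df["sticks"]
    g = df.groupby(["product_type", "segment", "month_ord"], as_index=False).agg(
        pw=("pw", "sum"), sticks=("sticks", "sum")
    )
    g["stick_price_gbp"] = g["pw"] / g["sticks"]
    return g[["product_type", "segment", "month_ord", "stick_price_gbp"]]


def postbudget_median_rise(
    series: pd.DataFrame,
    timeline: PolicyTimeline,
    focus_budget: Month = Month(2011, 3),
    value_col: str = "stick_price_gbp",
) -> pd.DataFrame:
    """Compare the price rise after one budget against typical rises.

    For each product type x segment price series: the monthly rise is
    price(m) - price(m-1); the post-budget rise of a budget enacted in
    month b is the rise at b+1. Returns, per series: the rise after
    *focus_budget*, the median post-budget rise over the other budget
    enactments, and the median monthly rise across the whole series.
    """
    budgets = timeline.budget_months()
    if focus_budget not in budgets:
        raise ValueError(f"{focus_budget} is not a budget enactment month")
    rows = []
    for (ptype, seg), grp in series.groupby(["product_type", "segment"]):
        grp = grp.sort_values("month_ord")
        prices = dict(zip(grp["month_ord"], grp[value_col]))
        rises = {
            o: prices[o] - prices[o - 1] for o in prices if (o - 1) in prices
        }
        if not rises:
            continue
        post = {
            b: rises.get(b.ordinal + 1)
            for b in budgets
            if rises.get(b.ordinal + 1) is not None
        }
        others = [v for b, v in post.items() if b != focus_budget]
        rows.append(
            {
                "product_type": ptype,
                "segment": seg,
                "focus_budget": str(focus_budget),
                "focus_rise_gbp": post.get(focus_budget, np.nan),
                "median_other_postbudget_rise_gbp": (
                    float(np.median(others)) if others else np.nan
                ),
                "median_monthly_rise_gbp": float(np.median(list(rises.values()))),
                "n_rises": len(rises),
            }
        )
    return pd.DataFrame(rows)


def segment_month_metrics(
    records: Sequence[SkuMonthRecord],
    assignments: SegmentAssignments,
    cpi: CpiSeries,
    *,
    eq: StickEquivalence = DEFAULT_EQ,
    pm_availability: Month = PM_AVAILABLE_FROM,
    single_packs_only: bool = True,
) -> pd.DataFrame:
    """One row per product type x segment x month: weighted average
    real pack and stick prices, sticks sold, real sales value, and
    price-marking prevalence/gap (NaN where unknown)."""
    df = panel_frame(records, cpi=cpi, eq=eq)
    df = df.merge(
        assignments.frame[["sku_id", "month_ord", "segment"]],
        on=["sku_id", "month_ord"],
        how="inner",
    )
    rows = []
    for (ptype, seg, month_ord), grp in df.groupby(
        ["product_type", "segment", "month_ord"]
    ):
        month = Month.from_ordinal(month_ord)
        priced = grp[grp["units"] > 0]
        if single_packs_only:
            priced = priced[~priced["multipack"]]
        row = {
            "product_type": ptype,
            "segment": seg,
            "month": str(month),
            "sticks_sold": grp["sticks"].sum(),
            "value_sold_real_gbp": float(
                np.nansum(priced["real_price_gbp"] * priced["units"])
            ),
            "wavg_real_pack_price_gbp": np.nan,
            "wavg_real_stick_price_gbp": np.nan,
            "pct_price_marked": np.nan,
            "pm_price_gap_pct": np.nan,
        }
        if len(priced):
            row["wavg_real_pack_price_gbp"] = _wavg(
                priced["real_price_gbp"].to_numpy(), priced["units"].to_numpy()
            )
            row["wavg_real_stick_price_gbp"] = _wavg(
                priced["real_stick_price_gbp"].to_numpy(), priced["sticks"].to_numpy()
            )
        if month >= pm_availability:
            known = priced[priced["price_marked"].notna()]
            if len(known):
                pm_arm = known[known["price_marked"] == True]  # noqa: E712
                non_arm = known[known["price_marked"] == False]  # noqa: E712
                row["pct_price_marked"] = (
                    pm_arm["units"].sum() / known["units"].sum() * 100.0
                )
                if len(pm_arm) and len(non_arm):
                    p_pm = _wavg(
                        pm_arm["real_price_gbp"].to_numpy(), pm_arm["units"].to_numpy()
                    )
                    p_non = _wavg(
                        non_arm["real_price_gbp"].to_numpy(),
                        non_arm["units"].to_numpy(),
                    )
                    row["pm_price_gap_pct"] = (p_pm - p_non) / p_non * 100.0
        rows.append(row)
    return pd.DataFrame(rows)
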