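"""Price-segment allocation of SKUs and the market-share eligibility
filter.

The market splits into price segments — premium, mid-price and value
for both product types, plus a fourth, cheaper "subvalue" FM segment
from its introduction date (default January 2012). Allocation follows
a two-source rule:

1. a curated dictionary (sku_id -> segment) wins wherever provided,
   mirroring allocation informed by commercial literature;
2. remaining SKUs are allocated by relative price: per product type
   and month, each SKU's volume-weighted mean real price per stick
   over a trailing window is cut at configurable quantiles of the
   cross-SKU stick-price distribution, and the assignment is sticky —
   a SKU only moves segment after its raw label has differed for a
   run of ``hysteresis_months`` consecutive months (prevents segment
   flapping around budget months).

Quantile cuts are scale-free, so assignments are invariant under
uniform price scaling within a month.

Before segmentation, SKUs are filtered for market relevance: a SKU is
eligible iff its share of within-product-type monthly stick volume
exceeded ``share_threshold`` (strict inequality) in at least
``min_months`` months, not necessarily consecutive.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .market_data import (
    DEFAULT_EQ,
    FM,
    CpiSeries,
    SkuMonthRecord,
    StickEquivalence,
    panel_frame,
)
from .months import Month

__all__ = [
    "SEGMENTS",
    "EligibilityFilter",
    "EligibilityResult",
    "SegmentationConfig",
    "SegmentAssignments",
    "apply_eligibility",
    "assign_segments",
]

#: Segment labels, cheapest last.
SEGMENTS = ("premium", "mid_price", "value", "subvalue")

#: Cheapest-to-priciest label orders used by the price rule.
_LABELS_3 = ("value", "mid_price", "premium")
_LABELS_4 = ("subvalue", "value", "mid_price", "premium")


@dataclass(frozen=True)
class EligibilityFilter:
    """Minimum market presence for a SKU to enter the analysis.

    Defaults: stick-volume share > 0.008% of its product type in at
    least 3 (not necessarily consecutive) months.
    """

    share_threshold: float = 0.00008
    min_months: int = 3


@dataclass
class EligibilityResult:
    eligible: set[str]
    qualifying_months: dict[str, int]
    #: per (sku_id, month) audit table with share and qualification flag
    audit: pd.DataFrame


def apply_eligibility(
    records: Sequence[SkuMonthRecord],
    filt: EligibilityFilter = EligibilityFilter(),
    eq: StickEquivalence = DEFAULT_EQ,
) -> EligibilityResult:
    """Compute eligible SKUs and a per-SKU-month share audit table.

    Shares are stick-equivalent volume shares within product type and
    month; the threshold comparison is strict (>).
    """
    if not records:
        raise ValueError("panel is empty")
    df = panel_frame(records, eq=eq)
    g = df.groupby(["product_type", "month_ord", "sku_id"], as_index=False)[
        "sticks"
    ].sum()
    totals = g.groupby(["product_type", "month_ord"])["sticks"].transform("sum")
    g["share"] = np.where(totals > 0, g["sticks"] / totals, 0.0)
    g["qualifies"] = g["share"] > filt.share_threshold
    counts = g.groupby("sku_id")["qualifies"].sum().astype(int)
    eligible = set(counts[counts >= filt.min_months].index)
    return EligibilityResult(
        eligible=eligible,
        qualifying_months=counts.to_dict(),
        audit=g,
    )


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the price rule.

    ``fm_cuts_pre`` / ``ryo_cuts`` are tercile-style boundaries mapping
    to (value, mid_price, premium); ``fm_cuts_post`` applies to FM from
    ``subvalue_start`` and maps to (subvalue, value, mid_price,
    premium).
    """

    window_months: int = 3
    hysteresis_months: int = 3
    subvalue_start: Month = Month(2012, 1)
    fm_cuts_pre: tuple[float, ...] = (1 / 3, 2 / 3)
    fm_cuts_post: tuple[float, ...] = (0.25, 0.5, 0.75)
    ryo_cuts: tuple[float, ...] = (1 / 3, 2 / 3)


class SegmentAssignments:
    """Per-SKU-month segment labels with provenance.

    Backed by a long DataFrame (sku_id, product_type, month_ord,
    segment, source); ``segment_of`` gives point lookup.
    """

    def __init__(self, frame: pd.DataFrame, unassigned: set[str] | None = None):
        self.frame = frame.reset_index(drop=True)
        self.unassigned = unassigned or set()
        self._map: dict[tuple[str, int], str] = {
            (s, o): seg
            for s, o, seg in zip(
                self.frame["sku_id"], self.frame["month_ord"], self.frame["segment"]
            )
        }

    def segment_of(self, sku_id: str, month: Month) -> str | None:
        return self._map.get((sku_id, month.ordinal))

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["month"] = out["month_ord"].map(lambda o: str(Month.from_ordinal(o)))
        return out[["sku_id", "product_type", "month", "segment", "source"]]

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _windowed_stick_prices(df: pd.DataFrame, window: int) -> pd.DataFrame:
    """Per SKU, trailing-window volume-weighted mean real stick price.

    The window is over the SKU's most recent *window* observed months
    (min one), weights are stick volumes.
    """
    df = df.sort_values(["sku_id", "month_ord"]).copy()
    df["pw"] = df["real_stick_price_gbp"] * df["sticks"]
    grp = df.groupby("sku_id")
    num = grp["pw"].rolling(window, min_periods=1).sum().reset_index(drop=True)
    den = grp["sticks"].rolling(window, min_periods=1).sum().reset_index(drop=True)
    df = df.reset_index(drop=True)
    df["window_price"] = num / den
    return df


def _smooth_labels(labels: list[str], hysteresis: int) -> list[str]:
    """Sticky assignment: adopt a new label only after it has persisted
    for *hysteresis* consecutive months."""
    if not labels:
        return []
    current = labels[0]
    pending: str | None = None
    streak = 0
    out = [current]
    for raw in labels[1:]:
        if raw == current:
            pending, streak = None, 0
        elif raw == pending:
            streak += 1
        else:
            pending, streak = raw, 1
        if pending is not None and streak >= hysteresis:
            current, pending, streak = pending, None, 0
        out.append(current)
    return out


def assign_segments(
    records: Sequence[SkuMonthRecord],
    cpi: CpiSeries,
    *,
    eq: StickEquivalence = DEFAULT_EQ,
    config: SegmentationConfig = SegmentationConfig(),
    dictionary: Mapping[str, str] | None = None,
    eligible: set[str] | None = None,
) -> SegmentAssignments:
    """Allocate each (eligible) SKU to one segment per month.

    *dictionary* entries take precedence over the price rule for every
    month the SKU appears (a "subvalue" dictionary label is reported as
    "value" before the subvalue introduction month). SKUs with no
    priced month are reported in ``result.unassigned``.
    """
    dictionary = dict(dictionary or {})
    for sku, seg in dictionary.items():
        if seg not in SEGMENTS:
            raise ValueError(f"dictionary maps {sku!r} to unknown segment {seg!r}")

    df = panel_frame(records, cpi=cpi, eq=eq)
    if eligible is not None:
        df = df[df["sku_id"].isin(eligible)]
    all_skus = set(df["sku_id"])
    priced = df[(df["units"] > 0)].dropna(subset=["real_stick_price_gbp"])
    unassigned = all_skus - set(priced["sku_id"])

    # one observation per SKU-month (stick-volume weighted across any
    # duplicate rows), then trailing-window smoothing
    per_sm = (
        priced.assign(pw=priced["real_stick_price_gbp"] * priced["sticks"])
        .groupby(["product_type", "sku_id", "month_ord"], as_index=False)
        .agg(pw=("pw", "sum"), sticks=("sticks", "sum"))
    )
    per_sm["real_stick_price_gbp"] = per_sm["pw"] / per_sm["sticks"]
    per_sm = _windowed_stick_prices(per_sm, config.window_months)

    sub_ord = config.subvalue_start.ordinal
    pieces = []
    for (ptype, month_ord), grp in per_sm.groupby(["product_type", "month_ord"]):
        if ptype == FM:
            cuts = config.fm_cuts_post if month_ord >= sub_ord else config.fm_cuts_pre
            labels = _LABELS_4 if month_ord >= sub_ord else _LABELS_3
        else:
            cuts, labels = config.ryo_cuts, _LABELS_3
        prices = grp["window_price"].to_numpy()
        bounds = np.quantile(prices, cuts)
        idx = np.searchsorted(bounds, prices, side="right")
        pieces.append(
            pd.DataFrame(
                {
                    "sku_id": grp["sku_id"].to_numpy(),
                    "product_type": ptype,
                    "month_ord": month_ord,
                    "raw_segment": [labels[i] for i in idx],
                }
            )
        )
    if not pieces:
        return SegmentAssignments(
            pd.DataFrame(
                columns=["sku_id", "product_type", "month_ord", "segment", "source"]
            ),
            unassigned,
        )
    raw = pd.concat(pieces, ignore_index=True).sort_values(["sku_id", "month_ord"])

    rows = []
    for sku, grp in raw.groupby("sku_id", sort=True):
        months = grp["month_ord"].to_list()
        ptype = grp["product_type"].iloc[0]
        if sku in dictionary:
            segs = [dictionary[sku]] * len(months)
            source = "dictionary"
        else:
            segs = _smooth_labels(grp["raw_segment"].to_list(), config.hysteresis_months)
            source = "price_rule"
        for m, seg in zip(months, segs):
            if seg == "subvalue" and m < sub_ord:
                seg = "value"
            rows.append((sku, ptype, m, seg, source))
    frame = pd.DataFrame(
        rows, columns=["sku_id", "product_type", "month_ord", "segment", "source"]
    )
    return SegmentAssignments(frame, unassigned)
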