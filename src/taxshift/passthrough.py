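"""Net-revenue time series and the post-budget change statistic.

Tax pass-through is read off the real net revenue per pack of a
segment's popular pack size: for each tax event (budget enactment,
optionally also the VAT-only changes, which the industry has been
observed to absorb), the delta series is

    delta(m) = real net revenue(m) - real net revenue(reference month)

for every month m after the event up to the next event. The default
reference is the enactment month itself (the construction used for
published post-budget figures); the month before enactment is
available as an alternative. A negative delta means the industry
absorbed part of the tax rise (undershifting: its per-pack take
fell), a positive delta means it raised prices by more than the tax
(overshifting), and zero means the rise was passed through exactly.

Because penny rounding makes an exact zero fragile, classification
uses a tolerance band (default 1 p) around zero.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .market_data import (
    DEFAULT_EQ,
    CpiSeries,
    SkuMonthRecord,
    StickEquivalence,
    panel_frame,
)
from .months import Month
from .segmentation import SegmentAssignments
from .tax_engine import PolicyTimeline, net_revenue_unrounded

__all__ = [
    "DEFAULT_PACK_CHOICE",
    "popular_pack_series",
    "postbudget_delta",
    "passthrough_table",
    "classify_shift",
    "ShiftSummary",
    "plot_net_revenue",
    "plot_deltas",
]

#: Popular pack size analysed per product type x segment: 20 sticks for
#: FM premium and mid-price, 19 for FM value and subvalue, 12.5 g RYO.
DEFAULT_PACK_CHOICE: dict[tuple[str, str], float] = {
    ("FM", "premium"): 20.0,
    ("FM", "mid_price"): 20.0,
    ("FM", "value"): 19.0,
    ("FM", "subvalue"): 19.0,
    ("RYO", "premium"): 12.5,
    ("RYO", "mid_price"): 12.5,
    ("RYO", "value"): 12.5,
}


def popular_pack_series(
    records: Sequence[SkuMonthRecord],
    assignments: SegmentAssignments,
    timeline: PolicyTimeline,
    cpi: CpiSeries,
    *,
    eq: StickEquivalence = DEFAULT_EQ,
    pack_choice: Mapping[tuple[str, str], float] | None = None,
    single_packs_only: bool = True,
    vat_mode: str = "net",
) -> pd.DataFrame:
    """Monthly volume-weighted real net revenue per pack, per segment,
    restricted to the segment's designated popular pack size.

    Months in which the pack size is absent are simply missing from the
    output (gaps are recorded, never interpolated). Columns:
    product_type, segment, pack_size, month_ord, real_net_revenue_gbp.
    """
    choice = dict(DEFAULT_PACK_CHOICE if pack_choice is None else pack_choice)
    df = panel_frame(records, cpi=cpi, eq=eq)
    if len(df) == 0:
        return pd.DataFrame(
            columns=[
                "product_type",
                "segment",
                "pack_size",
                "month_ord",
                "real_net_revenue_gbp",
            ]
        )
    df = df[df["units"] > 0]
    if single_packs_only:
        df = df[~df["multipack"]]
    df = df.merge(
        assignments.frame[["sku_id", "month_ord", "segment"]],
        on=["sku_id", "month_ord"],
        how="inner",
    )

    rows = []
    for (ptype, seg), grp in df.groupby(["product_type", "segment"]):
        size = choice.get((ptype, seg))
        if size is None:
            continue
        grp = grp[np.isclose(grp["pack_size"], size)]
        for month_ord, mgrp in grp.groupby("month_ord"):
            month = Month.from_ordinal(month_ord)
            policy = timeline.lookup(month)
            defl = cpi.deflator(month)
            # sub-penny unit values keep the series free of price
            # quantisation artefacts; reported deltas are in pence
            net = np.array(
                [
                    net_revenue_unrounded(p, ptype, size, policy, vat_mode=vat_mode)
                    for p in mgrp["price_gbp"]
                ]
            )
            rows.append(
                {
                    "product_type": ptype,
                    "segment": seg,
                    "pack_size": size,
                    "month_ord": month_ord,
                    "real_net_revenue_gbp": float(
                        np.average(net, weights=mgrp["units"]) * defl
                    ),
                }
            )
    columns = [
        "product_type",
        "segment",
        "pack_size",
        "month_ord",
        "real_net_revenue_gbp",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    out = pd.DataFrame(rows).sort_values(
        ["product_type", "segment", "month_ord"], ignore_index=True
    )
    out["month"] = out["month_ord"].map(lambda o: str(Month.from_ordinal(o)))
    return out


def postbudget_delta(
    series: Mapping[Month, float],
    enactment: Month,
    timeline: PolicyTimeline,
    *,
    next_event: Month | None = None,
    reference: str = "budget_month",
    include_vat_changes: bool = True,
) -> dict[Month, float]:
    """Delta series (pence) for one tax-event cycle of one revenue
    series (Month -> real net revenue GBP per pack).

    *enactment* must be a tax-change month of the timeline (a budget,
    or a VAT change when ``include_vat_changes``). Deltas run from the
    month after enactment up to (exclusive) the next event, or
    *next_event* / end of series if given. Months missing from the
    series appear as NaN.
    """
    events = timeline.budget_months(include_vat_changes=include_vat_changes)
    if enactment not in events:
        raise ValueError(f"{enactment} is not a tax-change month in the timeline")
    if reference == "budget_month":
        ref = enactment
    elif reference == "month_before":
        ref = enactment - 1
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if ref not in series:
        raise UndefinedMetricError(f"reference month {ref} not in series")
    if next_event is None:
        later = [e for e in events if e > enactment]
        next_event = min(later) if later else max(series, key=lambda m: m.ordinal) + 1
    base = series[ref]
    return {
        m: (series[m] - base) * 100.0 if m in series else float("nan")
        for m in (Month.from_ordinal(o) for o in range(enactment.ordinal + 1, next_event.ordinal))
    }


@dataclass(frozen=True)
class ShiftSummary:
    """Per-cycle summary of tax shifting.

    depth is the most negative delta (0 if never negative); duration
    counts the months from the start of the cycle until the delta first
    recovers to within *tolerance* of zero; end_delta is the last delta
    of the cycle.
    """

    depth_pence: float
    duration_months: int
    end_delta_pence: float


def classify_shift(
    deltas: Sequence[float], tolerance_pence: float = 1.0
) -> ShiftSummary:
    """Summarise one cycle's delta series (pence, cycle order)."""
    if len(deltas) == 0:
        raise ValueError("cycle has no deltas")
    arr = np.asarray(deltas, dtype=float)
    finite = arr[np.isfinite(arr)]
    depth = float(min(0.0, finite.min())) if len(finite) else float("nan")
    duration = 0
    for d in arr:
        if np.isfinite(d) and d < -tolerance_pence:
            duration += 1
        else:
            break
    end = float(finite[-1]) if len(finite) else float("nan")
    return ShiftSummary(depth_pence=depth, duration_months=duration, end_delta_pence=end)


def classify_month(delta_pence: float, tolerance_pence: float = 1.0) -> str:
    if not np.isfinite(delta_pence):
        return "gap"
    if delta_pence < -tolerance_pence:
        return "undershift"
    if delta_pence > tolerance_pence:
        return "overshift"
    return "fully_shifted"


def passthrough_table(
    series_frame: pd.DataFrame,
    timeline: PolicyTimeline,
    *,
    reference: str = "budget_month",
    include_vat_changes: bool = True,
    tolerance_pence: float = 1.0,
) -> pd.DataFrame:
    """Long table of per-month deltas for every segment series and
    every tax-event cycle covered by it.

    Input is the output of :func:`popular_pack_series`. Columns add
    cycle (the enactment month the delta refers to), delta_pence and a
    per-month classification.
    """
    events = timeline.budget_months(include_vat_changes=include_vat_changes)
    rows = []
    for (ptype, seg, size), grp in series_frame.groupby(
        ["product_type", "segment", "pack_size"]
    ):
        series = {
            Month.from_ordinal(o): v
            for o, v in zip(grp["month_ord"], grp["real_net_revenue_gbp"])
        }
        if not series:
            continue
        first, last = min(series), max(series)
        for event in events:
            if event < first or event > last:
                continue
            try:
                deltas = postbudget_delta(
                    series,
                    event,
                    timeline,
                    reference=reference,
                    include_vat_changes=include_vat_changes,
                )
            except UndefinedMetricError:
                continue
            for m, d in deltas.items():
                rows.append(
                    {
                        "product_type": ptype,
                        "segment": seg,
                        "pack_size": size,
                        "cycle": str(event),
                        "month": str(m),
                        "real_net_revenue_gbp": series.get(m, float("nan")),
                        "delta_pence": d,
                        "classification": classify_month(d, tolerance_pence),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Figure rendering (always to file, never interactive)


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_net_revenue(series_frame: pd.DataFrame, path: str | Path) -> None:
    """Line chart of real net revenue per pack by segment."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(9, 5))
    for (ptype, seg), grp in series_frame.groupby(["product_type", "segment"]):
        grp = grp.sort_values("month_ord")
        ax.plot(grp["month_ord"], grp["real_net_revenue_gbp"], label=f"{ptype} {seg}")
    ax.set_xlabel("month")
    ax.set_ylabel("real net revenue per pack (GBP)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_deltas(table: pd.DataFrame, path: str | Path) -> None:
    """Line chart of post-event net-revenue deltas by segment."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(9, 5))
    for (ptype, seg), grp in table.groupby(["product_type", "segment"]):
        grp = grp.sort_values("month")
        ax.plot(
            range(len(grp)), grp["delta_pence"], label=f"{ptype} {seg}", alpha=0.8
        )
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("months into cycle (concatenated cycles)")
    ax.set_ylabel("change in real net revenue vs budget month (pence)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
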