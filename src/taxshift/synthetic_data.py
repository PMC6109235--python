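"""Synthetic Scantrak-like monthly SKU panels with known ground truth.

Real UK point-of-sale tobacco panels are commercial and cannot be
redistributed, so every pipeline stage here is validated against
panels generated by this module, which plants the very structures the
pipeline is meant to recover:

* price-segmented SKUs with well-separated real stick-price bands,
* pack-size churn following per-year share schedules,
* price-marked SKUs sold at a fixed percentage discount,
* trending, seasonal, price-elastic volumes,
* and budget-synchronised pricing responses: at each tax event a
  segment absorbs a chosen number of pence per pack (undershifting),
  recoups it linearly over a chosen number of months, then drifts to a
  year-end overshoot target.

Prices are built by inverting the tax identity: a segment's target
real net revenue per pack plus the specific duty is grossed up through
the ad valorem and VAT wedge,

    price = (net + specific) / (1 - a - r/(1+r)),

so the generator knows the exact net revenue behind every price and
records it in a :class:`GroundTruthLedger`. Recombining the ledger's
tax components reproduces panel prices to the penny.

A single RNG stream (seeded in the scenario) drives all stochastic
draws in a fixed order: per segment — SKU price offsets, volume
weights, the price-marking permutation; then per month x SKU — price
noise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ScenarioError
from .market_data import (
    DEFAULT_EQ,
    FM,
    PM_AVAILABLE_FROM,
    RYO,
    CpiSeries,
    SkuMonthRecord,
    StickEquivalence,
)
from .months import Month, month_range
from .tax_engine import (
    PolicyTimeline,
    decompose_tax,
    round_pence,
    uk_timeline_2009_2015,
)

__all__ = [
    "ANNUAL_CPI_PCT",
    "synthetic_cpi",
    "ShiftPlan",
    "PackSizeSchedule",
    "SegmentSpec",
    "MarketScenario",
    "GroundTruthLedger",
    "generate",
    "default_paper_like_scenario",
    "single_segment_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
    "load_scenario",
    "save_scenario",
]

#: Published annual CPI 12-month percentage changes over the study
#: years, used to build the stylised monthly deflator below.
ANNUAL_CPI_PCT = {
    2008: 3.6,
    2009: 2.3,
    2010: 3.4,
    2011: 4.0,
    2012: 3.5,
    2013: 2.8,
    2014: 1.6,
    2015: 0.0,
}


def synthetic_cpi(
    start: Month = Month(2009, 1),
    end: Month = Month(2016, 6),
    base: Month = Month(2009, 1),
    annual_pct: dict[int, float] | None = None,
) -> CpiSeries:
    """Stylised monthly CPI: constant growth within each calendar year
    at that year's annual rate. Synthetic — a smooth stand-in for the
    official monthly index, not the published series.

    The base defaults to the first month so that the series round-trips
    through the CPI CSV dialect (whose reader takes the first row as
    base) without changing the deflation scale."""
    pct = dict(ANNUAL_CPI_PCT if annual_pct is None else annual_pct)
    index: dict[Month, float] = {}
    level = 100.0
    for m in month_range(start, end):
        index[m] = level
        year_pct = pct.get(m.year, pct[max(pct)])
        level *= (1.0 + year_pct / 100.0) ** (1.0 / 12.0)
    return CpiSeries(index=index, base_month=base)


@dataclass(frozen=True)
class ShiftPlan:
    """Budget-synchronised pricing response of one segment.

    At each tax event the segment's real net revenue per pack drops by
    ``absorb_pence`` (or by ``absorb_fraction`` of that event's
    per-pack tax rise, when ``absorb_pence`` is None), recovers
    linearly to baseline over ``recoup_months``, then drifts linearly
    to ``overshoot_pence`` above baseline by the end of the cycle.
    """

    absorb_pence: float | None = None
    absorb_fraction: float | None = None
    recoup_months: int = 0
    overshoot_pence: float = 0.0

    def __post_init__(self) -> None:
        if self.absorb_fraction is not None and not 0 <= self.absorb_fraction <= 1:
            raise ValueError("absorb_fraction must be in [0, 1]")
        if self.absorb_pence is not None and self.absorb_pence < 0:
            raise ValueError("absorb_pence must be >= 0")
        if self.recoup_months < 0:
            raise ValueError("recoup_months must be >= 0")


NO_SHIFT = ShiftPlan(absorb_pence=0.0, recoup_months=0, overshoot_pence=0.0)


@dataclass(frozen=True)
class PackSizeSchedule:
    """One pack size and its share of segment stick volume per year
    (step function: a missing year takes the latest earlier entry)."""

    size: float
    share_by_year: dict[int, float]

    def share(self, year: int) -> float:
        years = sorted(self.share_by_year)
        chosen = years[0]
        for y in years:
            if y <= year:
                chosen = y
        return self.share_by_year[chosen]


@dataclass(frozen=True)
class SegmentSpec:
    """Generating parameters of one product-type price segment."""

    product_type: str
    segment: str
    n_skus: int
    #: target real net revenue per stick, GBP (base-month money)
    real_net_per_stick_gbp: float
    pack_sizes: tuple[PackSizeSchedule, ...]
    #: segment stick-equivalent volume in the first generated month
    base_monthly_sticks: float
    annual_trend_pct: float = 0.0
    seasonal_amplitude: float = 0.06
    price_elasticity: float = -0.4
    pm_probability: float = 0.0
    pm_discount_pct: float = 0.0
    shift: ShiftPlan = NO_SHIFT
    #: first month the segment exists (None = scenario start)
    available_from: Month | None = None


@dataclass(frozen=True)
class MarketScenario:
    """Full description of a synthetic market."""

    start: Month
    end: Month
    segments: tuple[SegmentSpec, ...]
    #: sd of the pack-price noise added to each SKU-month's nominal
    #: net revenue, GBP
    price_noise_sd_gbp: float = 0.01
    #: sd of the fixed per-SKU offset to the segment's net per stick,
    #: GBP — makes SKUs within a segment distinct brands
    brand_spread_gbp_per_stick: float = 0.0015
    #: treat the VAT-only changes as tax events (absorption + cycle
    #: boundaries), as observed in the study window
    include_vat_events: bool = True
    pm_flag_available_from: Month = PM_AVAILABLE_FROM
    seed: int = 0

    def validate(self, timeline: PolicyTimeline, cpi: CpiSeries) -> None:
        if self.end < self.start:
            raise ScenarioError("end precedes start")
        if not self.segments:
            raise ScenarioError("scenario has no segments")
        for m in month_range(self.start, self.end):
            if m not in cpi:
                raise ScenarioError(f"CPI series does not cover {m}")
        try:
            timeline.lookup(self.start)
        except Exception as exc:
            raise ScenarioError(f"no tax policy at scenario start: {exc}") from None
        for spec in self.segments:
            if spec.product_type not in (FM, RYO):
                raise ScenarioError(f"bad product_type {spec.product_type!r}")
            if spec.segment == "subvalue" and spec.product_type != FM:
                raise ScenarioError("subvalue is an FM-only segment")
            if spec.n_skus < 1:
                raise ScenarioError("n_skus must be >= 1")
            if not spec.pack_sizes:
                raise ScenarioError(f"{spec.segment}: no pack sizes")
        self._check_band_separation(timeline, cpi)

    def _check_band_separation(self, timeline: PolicyTimeline, cpi: CpiSeries) -> None:
        """Adjacent segment stick-price bands must be >= 3 price-noise
        sd apart for the price rule to be recoverable."""
        eq = DEFAULT_EQ
        by_type: dict[str, list[tuple[float, str, float]]] = {}
        for spec in self.segments:
            first = spec.available_from or self.start
            ref = max(spec.pack_sizes, key=lambda s: s.share(first.year))
            spp = ref.size if spec.product_type == FM else ref.size / eq.grams_per_ryo_stick
            price = _baseline_real_price(
                spec.real_net_per_stick_gbp, spec.product_type, ref.size, spp,
                first, timeline, cpi,
            )
            noise_stick = self.price_noise_sd_gbp / spp
            by_type.setdefault(spec.product_type, []).append(
                (price, spec.segment, noise_stick)
            )
        for ptype, entries in by_type.items():
            entries.sort()
            for (p0, s0, n0), (p1, s1, n1) in zip(entries, entries[1:]):
                if p1 - p0 < 3.0 * max(n0, n1):
                    raise ScenarioError(
                        f"{ptype} segments {s0}/{s1} stick-price bands too close "
                        f"({p1 - p0:.4f} GBP) for noise sd"
                    )


def _wedge(policy) -> float:
    """1 - ad_valorem - vat wedge: the share of the retail price left
    after the two price-proportional taxes."""
    r = policy.vat_rate
    return 1.0 - policy.ad_valorem_rate - r / (1.0 + r)


def _specific_gbp(product_type: str, size: float, policy) -> float:
    rate = policy.specific_fm_per_1000 if product_type == FM else policy.specific_ryo_per_kg
    return rate * size / 1000.0


def _baseline_real_price(
    net_per_stick: float,
    product_type: str,
    size: float,
    spp: float,
    month: Month,
    timeline: PolicyTimeline,
    cpi: CpiSeries,
) -> float:
    """Real stick price implied by a net-per-stick target at a month's
    policy (no shifting, no noise)."""
    policy = timeline.lookup(month)
    net_real_pack = net_per_stick * spp
    spec = _specific_gbp(product_type, size, policy)
    real_pack = (net_real_pack + spec * cpi.deflator(month)) / _wedge(policy)
    return real_pack / spp


@dataclass
class GroundTruthLedger:
    """Exact bookkeeping behind a generated panel.

    ``sku_months``: one row per emitted record with the true tax
    decomposition of its price (recombining the components reproduces
    the price exactly) and the intended real net revenue target.
    ``injected``: one row per segment x tax event with the planted
    undershift depth, duration and overshoot.
    """

    sku_months: pd.DataFrame
    injected: pd.DataFrame
    scenario: MarketScenario

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.sku_months.to_csv(directory / "ledger.csv", index=False)
        self.injected.to_csv(directory / "injected.csv", index=False)


def _allocate_counts(n: int, weights: Sequence[float]) -> list[int]:
    """Split n items over weights: at least one each where weight > 0,
    remainder by largest share."""
    w = np.asarray(weights, dtype=float)
    w = np.where(w > 0, w, 0.0)
    if w.sum() == 0:
        w = np.ones_like(w)
    raw = w / w.sum() * n
    counts = np.maximum(np.floor(raw).astype(int), 1)
    while counts.sum() > n and (counts > 1).any():
        counts[np.argmax(counts)] -= 1
    order = np.argsort(-(raw - counts))
    i = 0
    while counts.sum() < n:
        counts[order[i % len(counts)]] += 1
        i += 1
    return counts.tolist()


def _tax_rise_pence(
    product_type: str, size: float, price_gbp: float, old_policy, new_policy
) -> float:
    """Per-pack tax increase at an event, evaluated at the pre-event
    price (the specific-duty jump plus any rate-change effects)."""
    old = decompose_tax(price_gbp, product_type, size, old_policy)
    new = decompose_tax(price_gbp, product_type, size, new_policy)
    return float(new.total_tax - old.total_tax)


def generate(
    scenario: MarketScenario,
    timeline: PolicyTimeline | None = None,
    cpi: CpiSeries | None = None,
    eq: StickEquivalence = DEFAULT_EQ,
) -> tuple[list[SkuMonthRecord], GroundTruthLedger]:
    """Generate a panel and its ground-truth ledger.

    Deterministic given ``scenario.seed``. Uses the shipped UK
    timeline and the stylised CPI when none are supplied.
    """
    timeline = timeline or uk_timeline_2009_2015()
    cpi = cpi or synthetic_cpi()
    scenario.validate(timeline, cpi)
    rng = np.random.default_rng(scenario.seed)
    months = month_range(scenario.start, scenario.end)
    events = [
        e
        for e in timeline.budget_months(
            include_vat_changes=scenario.include_vat_events
        )
        if scenario.start <= e <= scenario.end
    ]

    records: list[SkuMonthRecord] = []
    ledger_rows: list[dict] = []
    injected_rows: list[dict] = []

    for spec in scenario.segments:
        seg_start = spec.available_from or scenario.start
        seg_months = [m for m in months if m >= seg_start]
        if not seg_months:
            continue
        spp_of = (
            (lambda s: float(s))
            if spec.product_type == FM
            else (lambda s: s / eq.grams_per_ryo_stick)
        )

        # --- SKU roster (fixed RNG order: offsets, weights, PM perm) --
        # sizes get SKU counts by their mean share over the segment's
        # life, so late-growing sizes are represented throughout
        seg_years = range(seg_start.year, scenario.end.year + 1)
        counts = _allocate_counts(
            spec.n_skus,
            [
                float(np.mean([sched.share(y) for y in seg_years]))
                for sched in spec.pack_sizes
            ],
        )
        offsets = rng.normal(
            0.0, scenario.brand_spread_gbp_per_stick, size=spec.n_skus
        )
        weights = rng.uniform(0.7, 1.3, size=spec.n_skus)
        perm = rng.permutation(spec.n_skus)
        n_pm = round(spec.pm_probability * spec.n_skus)
        pm_flags = np.zeros(spec.n_skus, dtype=bool)
        pm_flags[perm[:n_pm]] = True

        skus = []  # (sku_id, schedule, offset, weight, pm)
        k = 0
        for sched, cnt in zip(spec.pack_sizes, counts):
            for j in range(cnt):
                sku_id = (
                    f"{spec.product_type}-{spec.segment}-{sched.size:g}-{j:02d}"
                )
                skus.append((sku_id, sched, offsets[k], weights[k], pm_flags[k]))
                k += 1

        # --- shift path: real pence adjustment per month ---------------
        path: dict[int, float] = {m.ordinal: 0.0 for m in seg_months}
        seg_events = [e for e in events if e >= seg_start]
        ref_sched = max(spec.pack_sizes, key=lambda s: s.share(seg_start.year))
        ref_spp = spp_of(ref_sched.size)
        for i, e in enumerate(seg_events):
            nxt = seg_events[i + 1] if i + 1 < len(seg_events) else scenario.end + 1
            cycle = [m for m in seg_months if e < m < nxt]
            if not cycle:
                continue
            if spec.shift.absorb_pence is not None:
                depth = float(spec.shift.absorb_pence)
            elif spec.shift.absorb_fraction is not None:
                old_p = timeline.lookup(e - 1)
                new_p = timeline.lookup(e)
                pre_real = _baseline_real_price(
                    spec.real_net_per_stick_gbp, spec.product_type,
                    ref_sched.size, ref_spp, e, timeline, cpi,
                ) * ref_spp
                pre_nominal = pre_real / cpi.deflator(e)
                depth = spec.shift.absorb_fraction * _tax_rise_pence(
                    spec.product_type, ref_sched.size, pre_nominal, old_p, new_p
                )
            else:
                depth = 0.0
            R = spec.shift.recoup_months
            K = len(cycle)
            for kk, m in enumerate(cycle, start=1):
                if R > 0 and kk <= R and depth > 0:
                    path[m.ordinal] = -depth * (1.0 - (kk - 1) / R)
                elif K > R and spec.shift.overshoot_pence:
                    path[m.ordinal] = (
                        spec.shift.overshoot_pence * (kk - R) / (K - R)
                    )
            injected_rows.append(
                {
                    "product_type": spec.product_type,
                    "segment": spec.segment,
                    "event": str(e),
                    "event_ord": e.ordinal,
                    "depth_pence": depth,
                    "recoup_months": R,
                    "injected_duration_months": min(R, K) if depth > 0 else 0,
                    "overshoot_pence": spec.shift.overshoot_pence,
                    "cycle_months": K,
                }
            )

        # --- volume scale path (deterministic) -------------------------
        p0 = _baseline_real_price(
            spec.real_net_per_stick_gbp, spec.product_type, ref_sched.size,
            ref_spp, seg_start, timeline, cpi,
        )

        # --- emit records ----------------------------------------------
        for m in seg_months:
            policy = timeline.lookup(m)
            defl = cpi.deflator(m)
            wedge = _wedge(policy)
            years_in = (m - seg_start) / 12.0
            seasonal = 1.0 - spec.seasonal_amplitude * math.cos(
                2.0 * math.pi * (m.month - 1) / 12.0
            )
            p_rel = (
                _baseline_real_price(
                    spec.real_net_per_stick_gbp, spec.product_type,
                    ref_sched.size, ref_spp, m, timeline, cpi,
                )
                / p0
            )
            seg_sticks = (
                spec.base_monthly_sticks
                * (1.0 + spec.annual_trend_pct / 100.0) ** years_in
                * seasonal
                * p_rel ** spec.price_elasticity
            )
            shares = np.array([s.share(m.year) for s in spec.pack_sizes])
            shares = shares / shares.sum() if shares.sum() > 0 else shares
            share_of = {s.size: sh for s, sh in zip(spec.pack_sizes, shares)}
            wsum_by_size: dict[float, float] = {}
            for _, sched, _, w, _ in skus:
                wsum_by_size[sched.size] = wsum_by_size.get(sched.size, 0.0) + w

            for sku_id, sched, offset, w, pm in skus:
                spp = spp_of(sched.size)
                sku_sticks = (
                    seg_sticks * share_of[sched.size] * w / wsum_by_size[sched.size]
                )
                units = int(round(sku_sticks / spp))
                if units < 1:
                    continue
                net_real_pack = (
                    (spec.real_net_per_stick_gbp + offset) * spp
                    + path[m.ordinal] / 100.0
                )
                net_nom = net_real_pack / defl
                if scenario.price_noise_sd_gbp > 0:
                    net_nom += rng.normal(0.0, scenario.price_noise_sd_gbp)
                price = (net_nom + _specific_gbp(spec.product_type, sched.size, policy)) / wedge
                if pm and spec.pm_discount_pct:
                    price *= 1.0 - spec.pm_discount_pct / 100.0
                if round_pence(price * 100.0) < 1:
                    raise ScenarioError(
                        f"{sku_id} {m}: non-positive price generated; "
                        "check net revenue targets"
                    )
                # monthly sales value is rounded to the penny at the
                # aggregate, so the derived unit value carries sub-penny
                # resolution, as in real point-of-sale extracts
                sales_pence = round_pence(price * 100.0 * units)
                flag = None if m < scenario.pm_flag_available_from else bool(pm)
                records.append(
                    SkuMonthRecord(
                        sku_id=sku_id,
                        brand_family=f"{spec.segment}_{spec.product_type}".lower(),
                        brand_variant=sku_id,
                        product_type=spec.product_type,
                        pack_size=sched.size,
                        multipack=False,
                        price_marked=flag,
                        month=m,
                        sales_value_pence=sales_pence,
                        units_sold=units,
                    )
                )
                # ledger taxes describe the panel exactly: decompose the
                # same unit value the pipeline will derive
                bd = decompose_tax(
                    sales_pence / units / 100.0, spec.product_type, sched.size, policy
                )
                ledger_rows.append(
                    {
                        "sku_id": sku_id,
                        "product_type": spec.product_type,
                        "segment": spec.segment,
                        "pack_size": sched.size,
                        "month": str(m),
                        "month_ord": m.ordinal,
                        "units": units,
                        "price_pence": bd.price,
                        "vat_pence": bd.vat,
                        "ad_valorem_pence": bd.ad_valorem,
                        "specific_pence": bd.specific,
                        "net_revenue_pence": bd.net_revenue,
                        "real_net_revenue_gbp": bd.net_revenue / 100.0 * defl,
                        "target_real_net_pack_gbp": net_real_pack,
                        "price_marked": bool(pm),
                        "pm_discount_pct": (
                            spec.pm_discount_pct if pm else 0.0
                        ),
                    }
                )

    ledger = GroundTruthLedger(
        sku_months=pd.DataFrame(ledger_rows),
        injected=pd.DataFrame(injected_rows),
        scenario=scenario,
    )
    return records, ledger


# ---------------------------------------------------------------------------
# Canned scenarios


def _ramp(y0: int, v0: float, y1: int, v1: float) -> dict[int, float]:
    """Linear per-year ramp from (y0, v0) to (y1, v1), inclusive."""
    if y1 == y0:
        return {y0: v0}
    return {
        y: v0 + (v1 - v0) * (y - y0) / (y1 - y0) for y in range(y0, y1 + 1)
    }


def default_paper_like_scenario(seed: int = 0) -> MarketScenario:
    """A 2009-2015 UK-like market: four FM segments (subvalue from
    January 2012) and three RYO segments, declining FM and growing RYO
    volumes, pack sizes shrinking over time, price-marking concentrated
    in the cheap segments, and tax absorption graded deepest in the
    cheapest segments. Stylised emulation of the published qualitative
    patterns, not a reproduction of any published figure."""
    fm = [
        SegmentSpec(
            FM, "premium", 12, 0.0650,
            (
                PackSizeSchedule(20.0, _ramp(2009, 0.92, 2015, 0.80)),
                PackSizeSchedule(10.0, _ramp(2009, 0.08, 2015, 0.20)),
            ),
            base_monthly_sticks=30e6, annual_trend_pct=-12.0,
            pm_probability=0.0, pm_discount_pct=0.0,
            shift=ShiftPlan(absorb_pence=5.0, recoup_months=2, overshoot_pence=20.0),
        ),
        SegmentSpec(
            FM, "mid_price", 12, 0.0475,
            (
                PackSizeSchedule(20.0, _ramp(2009, 0.90, 2015, 0.55)),
                PackSizeSchedule(10.0, _ramp(2009, 0.10, 2015, 0.45)),
            ),
            base_monthly_sticks=40e6, annual_trend_pct=-14.0,
            pm_probability=0.25, pm_discount_pct=4.0,
            shift=ShiftPlan(absorb_pence=8.0, recoup_months=3, overshoot_pence=10.0),
        ),
        SegmentSpec(
            FM, "value", 12, 0.0300,
            (
                PackSizeSchedule(20.0, _ramp(2009, 0.85, 2015, 0.05)),
                PackSizeSchedule(19.0, _ramp(2009, 0.15, 2015, 0.95)),
            ),
            base_monthly_sticks=20e6, annual_trend_pct=15.0,
            pm_probability=0.5, pm_discount_pct=5.0,
            shift=ShiftPlan(absorb_pence=12.0, recoup_months=5, overshoot_pence=4.0),
        ),
        SegmentSpec(
            FM, "subvalue", 12, 0.0125,
            (
                PackSizeSchedule(19.0, _ramp(2012, 0.80, 2015, 0.50)),
                PackSizeSchedule(18.0, _ramp(2012, 0.20, 2015, 0.50)),
            ),
            base_monthly_sticks=2e6, annual_trend_pct=60.0,
            pm_probability=0.8, pm_discount_pct=5.0,
            shift=ShiftPlan(absorb_pence=18.0, recoup_months=8, overshoot_pence=0.0),
            available_from=Month(2012, 1),
        ),
    ]
    ryo = [
        SegmentSpec(
            RYO, "premium", 9, 0.0475,
            (
                PackSizeSchedule(12.5, _ramp(2009, 0.82, 2015, 0.75)),
                PackSizeSchedule(50.0, _ramp(2009, 0.08, 2015, 0.11)),
                PackSizeSchedule(10.0, _ramp(2009, 0.10, 2015, 0.14)),
            ),
            base_monthly_sticks=6e6, annual_trend_pct=-9.0,
            pm_probability=0.3, pm_discount_pct=3.0,
            shift=ShiftPlan(absorb_pence=6.0, recoup_months=2, overshoot_pence=12.0),
        ),
        SegmentSpec(
            RYO, "mid_price", 9, 0.0350,
            (
                PackSizeSchedule(12.5, _ramp(2009, 0.69, 2015, 0.53)),
                PackSizeSchedule(10.0, _ramp(2009, 0.01, 2015, 0.17)),
                PackSizeSchedule(50.0, {2009: 0.30}),
            ),
            base_monthly_sticks=5e6, annual_trend_pct=10.0,
            pm_probability=0.5, pm_discount_pct=5.0,
            shift=ShiftPlan(absorb_pence=10.0, recoup_months=4, overshoot_pence=5.0),
        ),
        SegmentSpec(
            RYO, "value", 9, 0.0225,
            (
                PackSizeSchedule(12.5, _ramp(2009, 0.70, 2015, 0.60)),
                PackSizeSchedule(10.0, _ramp(2009, 0.05, 2015, 0.25)),
                PackSizeSchedule(50.0, _ramp(2009, 0.25, 2015, 0.15)),
            ),
            base_monthly_sticks=1.5e6, annual_trend_pct=15.0,
            pm_probability=0.5, pm_discount_pct=5.0,
            shift=ShiftPlan(absorb_pence=14.0, recoup_months=6, overshoot_pence=0.0),
        ),
    ]
    return MarketScenario(
        start=Month(2009, 1),
        end=Month(2015, 12),
        segments=tuple(fm + ryo),
        seed=seed,
    )


def single_segment_scenario(
    absorb_pence: float,
    recoup_months: int,
    seed: int,
    *,
    overshoot_pence: float = 0.0,
    n_skus: int = 48,
    start: Month = Month(2011, 1),
    end: Month = Month(2013, 12),
    price_noise_sd_gbp: float = 0.01,
) -> MarketScenario:
    """One FM segment of same-size SKUs — the minimal market used for
    parameter-recovery studies of the pass-through estimator. VAT-only
    changes are not treated as events, so measured cycles run budget to
    budget."""
    spec = SegmentSpec(
        FM, "value", n_skus, 0.0350,
        (PackSizeSchedule(20.0, {start.year: 1.0}),),
        base_monthly_sticks=10e6,
        annual_trend_pct=-5.0,
        pm_probability=0.0,
        shift=ShiftPlan(
            absorb_pence=absorb_pence,
            recoup_months=recoup_months,
            overshoot_pence=overshoot_pence,
        ),
    )
    return MarketScenario(
        start=start,
        end=end,
        segments=(spec,),
        price_noise_sd_gbp=price_noise_sd_gbp,
        include_vat_events=False,
        seed=seed,
    )


def truth_assignments(ledger: GroundTruthLedger):
    """Ledger-derived segment assignments (the oracle labelling)."""
    from .segmentation import SegmentAssignments

    frame = ledger.sku_months[
        ["sku_id", "product_type", "month_ord", "segment"]
    ].copy()
    frame["source"] = "ledger"
    return SegmentAssignments(frame)


# ---------------------------------------------------------------------------
# Scenario (de)serialisation — same YAML dialect as the tax timeline


def scenario_to_dict(s: MarketScenario) -> dict:
    return {
        "start": str(s.start),
        "end": str(s.end),
        "price_noise_sd_gbp": s.price_noise_sd_gbp,
        "brand_spread_gbp_per_stick": s.brand_spread_gbp_per_stick,
        "include_vat_events": s.include_vat_events,
        "pm_flag_available_from": str(s.pm_flag_available_from),
        "seed": s.seed,
        "segments": [
            {
                "product_type": sp.product_type,
                "segment": sp.segment,
                "n_skus": sp.n_skus,
                "real_net_per_stick_gbp": sp.real_net_per_stick_gbp,
                "pack_sizes": [
                    {"size": sched.size,
                     "share_by_year": {int(y): v for y, v in sched.share_by_year.items()}}
                    for sched in sp.pack_sizes
                ],
                "base_monthly_sticks": sp.base_monthly_sticks,
                "annual_trend_pct": sp.annual_trend_pct,
                "seasonal_amplitude": sp.seasonal_amplitude,
                "price_elasticity": sp.price_elasticity,
                "pm_probability": sp.pm_probability,
                "pm_discount_pct": sp.pm_discount_pct,
                "available_from": (
                    None if sp.available_from is None else str(sp.available_from)
                ),
                "shift": {
                    "absorb_pence": sp.shift.absorb_pence,
                    "absorb_fraction": sp.shift.absorb_fraction,
                    "recoup_months": sp.shift.recoup_months,
                    "overshoot_pence": sp.shift.overshoot_pence,
                },
            }
            for sp in s.segments
        ],
    }


def scenario_from_dict(data: dict) -> MarketScenario:
    segments = []
    for sp in data["segments"]:
        shift = sp.get("shift") or {}
        segments.append(
            SegmentSpec(
                product_type=sp["product_type"],
                segment=sp["segment"],
                n_skus=int(sp["n_skus"]),
                real_net_per_stick_gbp=float(sp["real_net_per_stick_gbp"]),
                pack_sizes=tuple(
                    PackSizeSchedule(
                        float(e["size"]),
                        {int(y): float(v) for y, v in e["share_by_year"].items()},
                    )
                    for e in sp["pack_sizes"]
                ),
                base_monthly_sticks=float(sp["base_monthly_sticks"]),
                annual_trend_pct=float(sp.get("annual_trend_pct", 0.0)),
                seasonal_amplitude=float(sp.get("seasonal_amplitude", 0.06)),
                price_elasticity=float(sp.get("price_elasticity", -0.4)),
                pm_probability=float(sp.get("pm_probability", 0.0)),
                pm_discount_pct=float(sp.get("pm_discount_pct", 0.0)),
                shift=ShiftPlan(
                    absorb_pence=shift.get("absorb_pence"),
                    absorb_fraction=shift.get("absorb_fraction"),
                    recoup_months=int(shift.get("recoup_months", 0)),
                    overshoot_pence=float(shift.get("overshoot_pence", 0.0)),
                ),
                available_from=(
                    None
                    if sp.get("available_from") in (None, "")
                    else Month.parse(sp["available_from"])
                ),
            )
        )
    return MarketScenario(
        start=Month.parse(data["start"]),
        end=Month.parse(data["end"]),
        segments=tuple(segments),
        price_noise_sd_gbp=float(data.get("price_noise_sd_gbp", 0.01)),
        brand_spread_gbp_per_stick=float(
            data.get("brand_spread_gbp_per_stick", 0.0015)
        ),
        include_vat_events=bool(data.get("include_vat_events", True)),
        pm_flag_available_from=Month.parse(
            data.get("pm_flag_available_from", str(PM_AVAILABLE_FROM))
        ),
        seed=int(data.get("seed", 0)),
    )


def load_scenario(path: str | Path) -> MarketScenario:
    with Path(path).open() as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def save_scenario(scenario: MarketScenario, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)
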