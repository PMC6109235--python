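"""Time-varying tobacco tax schedule and per-pack tax decomposition.

The UK levies three taxes on a pack of tobacco:

* specific duty — a fixed amount per 1000 sticks (FM) or per kilogram
  (RYO), independent of price;
* ad valorem duty — a fraction of the retail (tax-inclusive) pack
  price;
* VAT — a general sales tax of rate r on the pre-VAT amount, i.e. the
  VAT contained in a gross price P is P * r / (1 + r).

Net revenue — what manufacturer and retailer jointly retain — is the
pack price minus the sum of the three. Each component is rounded to
the penny (half-up) and net revenue is the pence residual, so the
accounting identity

    price = vat + ad_valorem + specific + net_revenue

holds exactly in pence for every decomposition.

An alternative ``vat_on_gross`` mode (vat = price * r, reading the
rate as a share of the gross price) is provided for sensitivity
analysis; the default is the standard UK mechanism above.
"""
from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

from .errors import NoPolicyError
from .market_data import FM, RYO, CpiSeries, SkuMonthRecord, unit_price
from .months import Month

__all__ = [
    "TaxPolicy",
    "PolicyTimeline",
    "TaxBreakdown",
    "lookup_policy",
    "decompose_tax",
    "net_revenue_real",
    "uk_timeline_2009_2015",
    "round_pence",
]

_FIXTURE = "uk_tobacco_tax_2009_2015.yaml"


def round_pence(x: float) -> int:
    """Round a pence amount to the nearest penny, halves away from zero.

    Deterministic half-up keeps hand-checked examples stable where
    banker's rounding would depend on float parity.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class TaxPolicy:
    """Tax rates in force from a given month.

    vat_rate and ad_valorem_rate are fractions (0.20, 0.165); specific
    duty is GBP per 1000 sticks (FM) / GBP per kg (RYO).
    ``is_budget_enactment`` distinguishes the annual tobacco budget
    from VAT-only changes, which did not occur on budget days.
    """

    effective_from: Month
    vat_rate: float
    ad_valorem_rate: float
    specific_fm_per_1000: float
    specific_ryo_per_kg: float
    is_budget_enactment: bool = False

    def __post_init__(self) -> None:
        for name in ("vat_rate", "ad_valorem_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.specific_fm_per_1000 < 0 or self.specific_ryo_per_kg < 0:
            raise ValueError("specific rates must be >= 0")


class PolicyTimeline:
    """Ordered sequence of :class:`TaxPolicy`; lookup returns the
    latest policy effective on or before a month."""

    def __init__(self, policies: Iterable[TaxPolicy]):
        self.policies: list[TaxPolicy] = sorted(
            policies, key=lambda p: p.effective_from.ordinal
        )
        if not self.policies:
            raise ValueError("timeline needs at least one policy")
        ords = [p.effective_from.ordinal for p in self.policies]
        if len(set(ords)) != len(ords):
            raise ValueError("policy effective_from months must be distinct")
        self._ords = ords

    def lookup(self, month: Month) -> TaxPolicy:
        i = bisect_right(self._ords, month.ordinal)
        if i == 0:
            raise NoPolicyError(
                f"no tax policy in force at {month} "
                f"(timeline starts {self.policies[0].effective_from})"
            )
        return self.policies[i - 1]

    def budget_months(self, include_vat_changes: bool = False) -> list[Month]:
        """Enactment months of budgets (optionally also VAT-only changes)."""
        return [
            p.effective_from
            for p in self.policies
            if p.is_budget_enactment or include_vat_changes
        ]

    @property
    def start(self) -> Month:
        return self.policies[0].effective_from

    # -- serialisation ------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "PolicyTimeline":
        policies = []
        for entry in data["policies"]:
            policies.append(
                TaxPolicy(
                    effective_from=Month.parse(entry["effective_from"]),
                    vat_rate=float(entry["vat_pct"]) / 100.0,
                    ad_valorem_rate=float(entry["ad_valorem_pct"]) / 100.0,
                    specific_fm_per_1000=float(entry["specific_fm_gbp_per_1000"]),
                    specific_ryo_per_kg=float(entry["specific_ryo_gbp_per_kg"]),
                    is_budget_enactment=bool(entry["budget_enactment"]),
                )
            )
        return cls(policies)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PolicyTimeline":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh))


def uk_timeline_2009_2015() -> PolicyTimeline:
    """The shipped UK timeline: every duty and VAT change Dec 2008 -
    Dec 2015, with budget enactments flagged."""
    ref = resources.files("taxshift.data").joinpath(_FIXTURE)
    return PolicyTimeline.from_dict(yaml.safe_load(ref.read_text()))


def lookup_policy(timeline: PolicyTimeline, month: Month) -> TaxPolicy:
    """Policy in force in *month*; a change effective mid-month governs
    the whole month."""
    return timeline.lookup(month)


@dataclass(frozen=True)
class TaxBreakdown:
    """Per-pack decomposition in integer pence.

    net_revenue may be negative (a price below total duty is flagged by
    the caller, never clamped).
    """

    price: int
    vat: int
    ad_valorem: int
    specific: int

    @property
    def total_tax(self) -> int:
        return self.vat + self.ad_valorem + self.specific

    @property
    def net_revenue(self) -> int:
        return self.price - self.total_tax

    def as_gbp(self) -> dict[str, float]:
        return {
            "price": self.price / 100,
            "vat": self.vat / 100,
            "ad_valorem": self.ad_valorem / 100,
            "specific": self.specific / 100,
            "total_tax": self.total_tax / 100,
            "net_revenue": self.net_revenue / 100,
        }


def specific_duty_pence(
    product_type: str, pack_size: float, policy: TaxPolicy
) -> int:
    """Specific duty on one pack, in pence (exactly linear in pack size
    before rounding)."""
    if product_type == FM:
        raw = policy.specific_fm_per_1000 * 100.0 * pack_size / 1000.0
    elif product_type == RYO:
        raw = policy.specific_ryo_per_kg * 100.0 * pack_size / 1000.0
    else:
        raise ValueError(f"unknown product_type {product_type!r}")
    return round_pence(raw)


def decompose_tax(
    price: float,
    product_type: str,
    pack_size: float,
    policy: TaxPolicy,
    *,
    vat_mode: str = "net",
) -> TaxBreakdown:
    """Decompose a GBP pack price into VAT, ad valorem, specific duty
    and net revenue.

    ``vat_mode="net"`` (default): VAT extracted from the gross price as
    price * r / (1 + r). ``vat_mode="gross"``: vat = price * r.
    Components are rounded to the penny independently; net revenue is
    the residual, so the identity is exact in pence.
    """
    if price < 0:
        raise ValueError(f"price must be >= 0, got {price}")
    if not pack_size > 0:
        raise ValueError(f"pack_size must be > 0, got {pack_size}")
    if vat_mode not in ("net", "gross"):
        raise ValueError(f"vat_mode must be 'net' or 'gross', got {vat_mode!r}")

    price_p = round_pence(price * 100.0)
    r = policy.vat_rate
    vat_raw = price_p * (r / (1.0 + r)) if vat_mode == "net" else price_p * r
    return TaxBreakdown(
        price=price_p,
        vat=round_pence(vat_raw),
        ad_valorem=round_pence(price_p * policy.ad_valorem_rate),
        specific=specific_duty_pence(product_type, pack_size, policy),
    )


def net_revenue_unrounded(
    price: float,
    product_type: str,
    pack_size: float,
    policy: TaxPolicy,
    *,
    vat_mode: str = "net",
) -> float:
    """Net revenue in GBP without pence quantisation.

    Scanner unit values (monthly sales value / packs) carry sub-penny
    resolution; time-series statistics built on them use this exact
    decomposition, while :func:`decompose_tax` remains the penny-exact
    accounting view.
    """
    if price < 0:
        raise ValueError(f"price must be >= 0, got {price}")
    if vat_mode not in ("net", "gross"):
        raise ValueError(f"vat_mode must be 'net' or 'gross', got {vat_mode!r}")
    r = policy.vat_rate
    vat = price * (r / (1.0 + r)) if vat_mode == "net" else price * r
    if product_type == FM:
        specific = policy.specific_fm_per_1000 * pack_size / 1000.0
    elif product_type == RYO:
        specific = policy.specific_ryo_per_kg * pack_size / 1000.0
    else:
        raise ValueError(f"unknown product_type {product_type!r}")
    return price - vat - price * policy.ad_valorem_rate - specific


def net_revenue_real(
    record: SkuMonthRecord,
    timeline: PolicyTimeline,
    cpi: CpiSeries,
    *,
    vat_mode: str = "net",
) -> float:
    """Real (CPI-deflated, base-month GBP) net revenue per pack for one
    record, from its derived unit price and the policy of its month."""
    policy = timeline.lookup(record.month)
    breakdown = decompose_tax(
        unit_price(record), record.product_type, record.pack_size, policy,
        vat_mode=vat_mode,
    )
    return cpi.to_real(breakdown.net_revenue / 100.0, record.month)
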