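# Methods

`taxshift` analyses how tobacco companies price factory-made (FM)
cigarettes and roll-your-own (RYO) tobacco under a rising tax
schedule, using monthly SKU-level scanner data. This note documents
the models, conventions and numerical choices behind each stage, and
what the synthetic validation data do and do not establish.

## Tax model

Three taxes apply to a pack in the UK over 2009–2015:

* **specific duty** — a fixed amount per 1000 sticks (FM) or per
  kilogram (RYO), so a 20-stick pack at £189.49/1000 carries £3.79 and
  a 12.5 g pouch at £185.74/kg carries £2.32;
* **ad valorem duty** — a fraction *a* of the retail (tax-inclusive)
  pack price;
* **VAT** — rate *r* on the pre-VAT amount; the VAT contained in a
  gross price *P* is *P·r/(1+r)*.

Net revenue — what manufacturer and retailer jointly retain — is

    N = P − P·r/(1+r) − a·P − S.

The shipped policy timeline covers every duty and VAT change from
December 2008 to December 2015, with annual budget enactments flagged
separately from the two VAT-only changes (January 2010, January 2011).
A pre-study baseline row (December 2008) is derived from the 2009
budget's across-the-board 2% uplift so that panels starting January
2009 are covered; it is marked as derived in the fixture.

Two accounting views coexist deliberately:

* `decompose_tax` is the penny-exact view: each component is rounded
  half-up to the penny and net revenue is the pence residual, so
  `price = vat + ad_valorem + specific + net_revenue` holds exactly in
  integer pence for any input. This is the view used for the worked
  calculator, the ledger and all identity checks.
* `net_revenue_unrounded` keeps sub-penny resolution. Scanner unit
  values (monthly sales value ÷ packs sold) are not integer pence, and
  time-series statistics built from them should not re-quantise:
  rounding each month to the penny superimposes a sawtooth on a
  slowly drifting price that does not average out across SKUs sharing
  the same price, and can contribute spurious ±1 p excursions to
  month-on-month differences. The pass-through series therefore uses
  the exact decomposition; reported deltas are still stated in pence.

An alternative `vat_on_gross` mode (VAT read as a share of the gross
price, vat = *P·r*) is available as a sensitivity switch; the default
is the standard UK mechanism above.

Mid-month tax changes (UK budgets fall on the 18th–24th) are
attributed to the calendar month containing them: nothing in the
pipeline is day-resolved.

## Prices, deflation and stick equivalence

The unit pack price is always derived as sales_value / units_sold —
value, volume and price cannot disagree. Records with zero units have
an undefined price and are skipped, never imputed as zero. Money is
held in integer pence internally.

Real prices deflate nominal prices to base-month money with a monthly
CPI series: real = nominal × index[base]/index[month]. Missing
deflator months are hard errors; interpolating silently would corrupt
real-price trends. The package ships no official CPI series; any
monthly index can be supplied as CSV, and
`synthetic_data.synthetic_cpi()` provides a stylised substitute with
constant within-calendar-year growth matching the study years' annual
rates (2009: 2.3% … 2015: 0.0%). The synthetic index is smooth by
construction and carries none of the month-to-month variation of a
real CPI.

RYO weight converts to stick equivalents at 0.5 g per stick (the
survey-based average weight of a hand-rolled cigarette in the UK), so
12.5 g ≡ 25 sticks; the ratio is configurable.

## Eligibility and segmentation

To suppress small-number anomalies, analysis is restricted to SKUs
whose share of within-product-type monthly stick volume exceeded
0.008% (strict) in at least 3 months, not necessarily consecutive.
The filter is monotone: loosening either parameter never removes an
eligible SKU.

Segment allocation uses two sources in order of precedence:

1. an optional curated dictionary (sku_id → segment), representing
   externally known brand positioning;
2. a price rule: per product type and month, each SKU's
   volume-weighted mean real stick price over a trailing 3-month
   window is cut at quantiles of the cross-SKU distribution —
   terciles mapping to (value, mid-price, premium), and for FM from
   the subvalue introduction month (default January 2012) quartiles
   mapping to (subvalue, value, mid-price, premium). Assignments are
   sticky: a SKU moves segment only after its raw label has differed
   for 3 consecutive months (hysteresis), preventing flapping around
   budget months when prices move discontinuously.

Design choices worth knowing: quantile cuts are computed unweighted
across the SKUs present in a month (scale-free, so uniform price
inflation cannot re-segment the market); a boundary price falls in the
upper segment; a "subvalue" label is reported as "value" before the
introduction month. The concrete rule is a documented, configurable
stand-in for proprietary allocation practice — its outputs should not
be presented as any published brand dictionary.

## Market metrics

All price metrics are volume-weighted real prices: pack prices weight
by packs sold (all pack sizes pooled), stick prices by sticks sold.
Price metrics default to single packs; volume metrics include
everything. Weighted averages are bounded by the slice's min/max price
and invariant to record order. Medians over an even count use the
midpoint convention.

Price-marking (the retail price printed on the pack) is tri-state:
the flag only exists in the source data from August 2011, so months
before that yield an explicit unknown — never zero — and unknown-flag
records never enter a denominator. The PM price gap is the percentage
difference between the volume-weighted real price of PM and non-PM
packs. Because pack sizes differ in price by construction, a gap
computed across mixed sizes confounds the discount with the size mix;
the validation tests measure it within one pack size.

The budget-response comparison computes, per segment, the monthly
rise in the weighted real stick price, the rise in the month
immediately after a chosen budget enactment, the median rise following
the other enactments, and the median rise over the whole series. Real
(deflated) prices are used by default; nominal is a switch. Note a
timing convention: because a mid-month enactment governs its whole
month here, the tax-driven price jump lands in the enactment month
itself, and the month-after rise reflects the industry's absorption
response (negative when absorption outweighs drift) rather than the
pass-through jump.

## Pass-through statistic

For each segment the analysis tracks the volume-weighted real net
revenue per pack of one designated popular pack size (20 sticks for FM
premium and mid-price, 19 for FM value and subvalue, 12.5 g for RYO).
For each tax event *e* (budget enactment; optionally also the VAT-only
changes, which the industry has been observed to absorb) the delta
series is

    delta(m) = revenue(m) − revenue(e),   e < m < next event.

The reference month is the enactment month (the construction used in
the published post-budget figures); using the month before enactment
instead is a switch. delta < 0 is undershifting (the industry absorbed
part of the rise), delta > 0 overshifting, with a ±1 p tolerance band
because penny data make exact zeros fragile. Per cycle,
`classify_shift` reports undershift depth (most negative delta),
duration (months until the delta first recovers to within tolerance)
and the end-of-cycle delta. Months in which the pack size is absent
are gaps, never interpolated.

## Synthetic market generator

Real UK scanner panels are commercial; every pipeline stage is instead
validated on generated panels whose ground truth is known exactly.
Prices are built by inverting the tax identity: a segment's target
real net revenue per pack, plus specific duty, grossed up through the
ad valorem and VAT wedge, P = (N + S)/(1 − a − r/(1+r)). The
generator therefore knows the exact net revenue behind every price and
records it, with the full tax decomposition of each SKU-month, in a
ledger whose components recombine to the panel price exactly.

Pricing dynamics per segment: real net revenue is constant at target
(so absent a strategy, every tax change passes through to price in
full and prices otherwise track CPI); at each tax event the segment
absorbs a chosen number of pence per pack (or a fraction of the
event's per-pack tax rise), recoups linearly over a chosen number of
months, then drifts to a year-end overshoot target. Volumes follow
trend × seasonal (January trough) × a constant-elasticity response to
the segment's own real stick price; pack-size shares follow per-year
step schedules realised by reallocating volume across SKUs; PM status
is a fixed SKU attribute (the expected count per segment, selected by
a seeded permutation) with a fixed percentage discount that comes out
of net revenue. Monthly sales values are rounded to the penny at the
aggregate, so derived unit values carry sub-penny resolution, as in
real point-of-sale extracts. A single seeded RNG stream drives all
draws in a documented order, making panels bit-reproducible.

The default scenario (2009–2015, four FM segments with subvalue from
2012, three RYO segments) emulates the qualitative patterns of the
study period — declining FM and growing RYO volumes, shrinking pack
sizes (including a 10 g RYO share ramp from 1% to 17%), price-marking
concentrated in cheap segments, absorption graded deepest in the
cheapest segments (5 p/2 months for FM premium up to 18 p/8 months
for FM subvalue). These are emulation targets chosen once, not
calibrated reproductions of any published figure. Sizing is driven by
an error budget: each popular pack size carries at least six SKUs so
that residual quantisation and noise average well inside the 1 p
classification tolerance, and segment net-revenue ladders are spaced
so that PM discounts cannot push a segment's discounted SKUs across
the adjacent price band.

What passing on synthetic data does not show: the generator has no
cross-segment substitution matrix (downtrading is approximated by
opposite-signed volume trends), no store or region structure, no
entry/exit of SKUs other than the subvalue launch, no multipacks by
default, and price noise is i.i.d. Gaussian on net revenue. Recovery
results demonstrate the estimators are unbiased and sharp under the
stated data-generating process, not that real markets satisfy it.

## Parameter-recovery study design

The undershift recovery grid injects depths {5, 10, 18} p × recoup
horizons {2, 4, 6} months into a minimal one-segment market
(2011–2013, 48 same-size SKUs, default 1 p price noise) over 20 seeds
and requires depth back within ±2 p and duration within ±1 month in
every one of the 540 budget cycles. The panel size follows from the
error budget: the budget-month reference value's error is shared by
every delta in its cycle, so the weighted-mean error must be held
near 0.2 p for threshold-crossing misclassification to be negligible;
48 SKUs at ~1.1 p per-SKU error achieves that. Recovery uses
ledger-true segment labels to isolate the pass-through estimator from
the segment labeller (which is scored separately at ≥95% label
agreement); the CLI `recover` command runs the two together end to
end with a correspondingly wider default depth tolerance (3 p).

A deterministic edge is accepted rather than hidden: with depth 5 p
and recoup 6 months the true path's last undershot month sits at
−0.83 p, inside the ±1 p band, so measured duration is 5 — within the
stated ±1 month.

## Degenerate inputs and numerical conventions

Pence rounding is half-up (away from zero), so hand-checked examples
do not depend on float parity. Zero-units records: undefined price,
skipped. Empty metric slices: explicit undefined signal, not zero.
Negative net revenue (price below total duty): flagged, never
clamped. Specific duty is exactly linear in pack size before
rounding; after penny rounding, doubling pack size matches doubled
duty to ≤1 p. Timeline lookup is binary search over effective months;
a month before the first policy is an error, not a default. All CSV
outputs are deterministic given seed and config; run manifests record
the effective configuration, its hash and library versions, and
contain no timestamps or absolute paths.
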