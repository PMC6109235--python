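# taxshift

Tobacco tax pass-through analysis of monthly scanner panels.

Tobacco tax rises only curb smoking if they reach the shelf price.
The industry can blunt them: absorbing a duty increase for a few
months (**undershifting**, its per-pack take falls), then raising
prices by more than the tax later in the year (**overshifting**) — and
doing so differentially, keeping the cheapest factory-made (FM) and
roll-your-own (RYO) segments cheap through small packs and
price-marked packs. `taxshift` is a pipeline for measuring exactly
that in SKU-level point-of-sale data, for researchers and tax-policy
analysts working with commercial scanner panels.

For a pack price *P* under a policy with VAT rate *r*, ad valorem rate
*a* and specific duty *S* (per 1000 sticks for FM, per kg for RYO),
net revenue — what manufacturer and retailer jointly retain — is

    N = P − P·r/(1+r) − a·P − S

and the pass-through statistic for a tax event enacted in month *e* is
the real (CPI-deflated) net-revenue change of a segment's popular pack
size, Δ(m) = N̄(m) − N̄(e) for each following month up to the next
event: Δ < 0 means the rise was partly absorbed, Δ > 0 overshifted,
Δ = 0 fully passed through.

The package provides:

* `tax_engine` — the UK tobacco tax timeline 2009–2015 (every duty
  and VAT change, budget enactments flagged) and a penny-exact per-pack
  decomposition into VAT / ad valorem / specific / net revenue;
* `market_data` — the panel data model (SKU × month: sales value,
  units, pack size, multipack and price-marked flags), CSV dialects,
  CPI deflation, 0.5 g/stick RYO stick equivalence;
* `segmentation` — the >0.008%-share-in-≥3-months eligibility filter
  and price-segment allocation (premium / mid-price / value, plus FM
  subvalue from 2012): dictionary-first, then quantile cuts on
  trailing-window real stick prices with hysteresis;
* `metrics` — volume-weighted real pack/stick prices, stick volumes,
  annual pack-size share tables, price-marking prevalence and price
  gaps, and the post-budget median price-rise comparison;
* `passthrough` — popular-pack net-revenue series, post-budget delta
  series and undershift depth/duration classification;
* `synthetic_data` — a Scantrak-like market generator with a
  ground-truth ledger (exact taxes and net revenue behind every
  price, injected undershift depths), so every estimator is validated
  by parameter recovery without any proprietary data;
* `cli` — `taxshift taxcalc | simulate | analyze | recover`.

## Worked example

What does the taxman take from a £8.00 premium 20-pack in June 2015,
and what is left?

```text
$ taxshift taxcalc 8.00 FM 20 2015-06
policy in force from 2015-03 (budget enactment: True)
       price: £8.00
         vat: £1.33
  ad_valorem: £1.32
    specific: £3.79
   total_tax: £6.44
 net_revenue: £1.56
```

VAT is £8.00 × 0.2/1.2, ad valorem 16.5% of the pack price, specific
duty £189.49 per 1000 sticks × 20 — in total 80% of the price is tax,
and £1.56 per pack remains for manufacturer and retailer together.
The identity price = vat + ad valorem + specific + net revenue holds
exactly in pence for every decomposition.

A full synthetic run — generate a 2009–2015 market with known injected
pricing behaviour, analyse it blind, then compare what the pipeline
recovered against what was planted:

```sh
taxshift simulate --out runs/sim --seed 1
taxshift analyze --panel runs/sim/panel.csv --cpi runs/sim/cpi.csv \
        --out runs/analysis --plots
taxshift recover --simdir runs/sim --out runs/recovery
```

`analyze` writes eligibility, segment assignments, per-segment-month
metrics, volumes, pack-size shares, the net-revenue series and the
post-budget delta table (plus figures); `recover` prints
`recovery: 58/58 cycles within tolerance` and writes a per-cycle table
of injected vs recovered undershift depth and duration.

## Data access

Nielsen Scantrak and comparable scanner panels are commercial and are
not distributed here. The CSV dialects (documented in
`market_data`) are deliberately minimal so that an extract of any
SKU-level monthly panel — plus any monthly CPI CSV — can be analysed
with `taxshift analyze`. See `docs/methods.md` for the model details,
generator design and known limitations.
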