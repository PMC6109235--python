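# UK tobacco tax timeline, December 2008 - December 2015.
#
# One entry per change in any rate. Budget enactments (the annual
# tobacco budget, March except April in 2009) are flagged
# budget_enactment: true; the two VAT-only changes (January 2010 and
# January 2011) carry the duty rates forward unchanged and are flagged
# false. Rates: vat_pct is the sales-tax rate in percent (applied to
# the pre-VAT amount, i.e. extracted from the gross price as
# price * r / (1 + r)); ad_valorem_pct is percent of the retail
# (tax-inclusive) pack price; specific duty is GBP per 1000 sticks for
# factory-made cigarettes and GBP per kilogram for roll-your-own.
#
# The 2008-12 entry is a pre-study baseline so that panels starting in
# January 2009 are covered: its specific rates are the April-2009
# rates backed out of the budget's stated 2% across-the-board increase
# (114.31 / 1.02 and 124.45 / 1.02).
policies:
  - effective_from: 2008-12
    vat_pct: 15.0
    ad_valorem_pct: 24.0
    specific_fm_gbp_per_1000: 112.07
    specific_ryo_gbp_per_kg: 122.01
    budget_enactment: false
    note: pre-study baseline (derived, not a published budget row)
  - effective_from: 2009-04
    vat_pct: 15.0
    ad_valorem_pct: 24.0
    specific_fm_gbp_per_1000: 114.31
    specific_ryo_gbp_per_kg: 124.45
    budget_enactment: true
  - effective_from: 2010-01
    vat_pct: 17.5
    ad_valorem_pct: 24.0
    specific_fm_gbp_per_1000: 114.31
    specific_ryo_gbp_per_kg: 124.45
    budget_enactment: false
    note: VAT-only change
  - effective_from: 2010-03
    vat_pct: 17.5
    ad_valorem_pct: 24.0
    specific_fm_gbp_per_1000: 119.03
    specific_ryo_gbp_per_kg: 129.59
    budget_enactment: true
  - effective_from: 2011-01
    vat_pct: 20.0
    ad_valorem_pct: 24.0
    specific_fm_gbp_per_1000: 119.03
    specific_ryo_gbp_per_kg: 129.59
    budget_enactment: false
    note: VAT-only change
  - effective_from: 2011-03
    vat_pct: 20.0
    ad_valorem_pct: 16.5
    specific_fm_gbp_per_1000: 154.95
    specific_ryo_gbp_per_kg: 151.90
    budget_enactment: true
  - effective_from: 2012-03
    vat_pct: 20.0
    ad_valorem_pct: 16.5
    specific_fm_gbp_per_1000: 167.41
    specific_ryo_gbp_per_kg: 164.11
    budget_enactment: true
  - effective_from: 2013-03
    vat_pct: 20.0
    ad_valorem_pct: 16.5
    specific_fm_gbp_per_1000: 176.22
    specific_ryo_gbp_per_kg: 172.74
    budget_enactment: true
  - effective_from: 2014-03
    vat_pct: 20.0
    ad_valorem_pct: 16.5
    specific_fm_gbp_per_1000: 184.10
    specific_ryo_gbp_per_kg: 180.46
    budget_enactment: true
  - effective_from: 2015-03
    vat_pct: 20.0
    ad_valorem_pct: 16.5
    specific_fm_gbp_per_1000: 189.49
    specific_ryo_gbp_per_kg: 185.74
    budget_enactment: true
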