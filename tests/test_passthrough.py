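"""Net-revenue series, post-budget deltas and shift classification."""
import numpy as np
import pandas as pd
import pytest

from taxshift.market_data import SkuMonthRecord
from taxshift.months import Month, month_range
from taxshift.passthrough import (
    DEFAULT_PACK_CHOICE,
    ShiftSummary,
    classify_shift,
    passthrough_table,
    popular_pack_series,
    postbudget_delta,
)
from taxshift.segmentation import SegmentAssignments
from taxshift.synthetic_data import (
    generate,
    single_segment_scenario,
    truth_assignments,
)

GRID_CHOICE = {("FM", "value"): 20.0}


def one_sku_assignment(sku, months, ptype="FM", segment="premium"):
    return SegmentAssignments(
        pd.DataFrame(
            {
                "sku_id": sku,
                "product_type": ptype,
                "month_ord": [m.ordinal for m in months],
                "segment": segment,
                "source": "ledger",
            }
        )
    )


class TestPopularPackSeries:
    def test_default_pack_choice_values(self):
        assert DEFAULT_PACK_CHOICE[("FM", "premium")] == 20
        assert DEFAULT_PACK_CHOICE[("FM", "mid_price")] == 20
        assert DEFAULT_PACK_CHOICE[("FM", "value")] == 19
        assert DEFAULT_PACK_CHOICE[("FM", "subvalue")] == 19
        for seg in ("premium", "mid_price", "value"):
            assert DEFAULT_PACK_CHOICE[("RYO", seg)] == 12.5

    def test_single_sku_series_is_its_net_revenue(self, timeline, cpi):
        from taxshift.tax_engine import net_revenue_real

        months = month_range(Month(2013, 1), Month(2013, 6))
        records = [
            SkuMonthRecord(
                sku_id="solo", brand_family="f", brand_variant="v",
                product_type="FM", pack_size=20.0, multipack=False,
                price_marked=None, month=m,
                sales_value_pence=75100 + 10 * i, units_sold=100,
            )
            for i, m in enumerate(months)
        ]
        asg = one_sku_assignment("solo", months)
        series = popular_pack_series(records, asg, timeline, cpi)
        assert len(series) == len(months)
        for rec, (_, row) in zip(records, series.iterrows()):
            # independent closed form: price less the two price-
            # proportional taxes less specific duty, deflated
            price = rec.sales_value_pence / rec.units_sold / 100
            policy = timeline.lookup(rec.month)
            r = policy.vat_rate
            expected = (
                price * (1 - policy.ad_valorem_rate - r / (1 + r))
                - policy.specific_fm_per_1000 * 20 / 1000
            ) * cpi.deflator(rec.month)
            assert row["real_net_revenue_gbp"] == pytest.approx(expected, abs=1e-9)
            # and within a penny of the pence-exact accounting view
            assert row["real_net_revenue_gbp"] == pytest.approx(
                net_revenue_real(rec, timeline, cpi), abs=0.011
            )

    def test_missing_pack_size_months_are_gaps(self, timeline, cpi):
        months = month_range(Month(2013, 1), Month(2013, 4))
        records = [
            SkuMonthRecord(
                sku_id="solo", brand_family="f", brand_variant="v",
                product_type="FM", pack_size=20.0 if m.month != 2 else 10.0,
                multipack=False, price_marked=None, month=m,
                sales_value_pence=75000, units_sold=100,
            )
            for m in months
        ]
        asg = one_sku_assignment("solo", months)
        series = popular_pack_series(records, asg, timeline, cpi)
        assert len(series) == 3  # February (10-pack only) is a gap
        assert Month(2013, 2).ordinal not in set(series["month_ord"])


class TestPostbudgetDelta:
    def _flat_series(self, start, end, level=1.5):
        return {m: level for m in month_range(start, end)}

    def test_flat_series_all_zero(self, timeline):
        series = self._flat_series(Month(2012, 1), Month(2013, 6))
        deltas = postbudget_delta(series, Month(2012, 3), timeline)
        assert set(deltas) == set(month_range(Month(2012, 4), Month(2013, 2)))
        assert all(d == pytest.approx(0.0) for d in deltas.values())

    def test_non_event_month_rejected(self, timeline):
        series = self._flat_series(Month(2012, 1), Month(2013, 6))
        with pytest.raises(ValueError):
            postbudget_delta(series, Month(2012, 7), timeline)

    def test_reference_modes_differ_by_enactment_move(self, timeline):
        series = self._flat_series(Month(2012, 1), Month(2013, 2))
        series[Month(2012, 3)] = 1.40  # enactment month dips 10 p
        d_budget = postbudget_delta(series, Month(2012, 3), timeline)
        d_before = postbudget_delta(
            series, Month(2012, 3), timeline, reference="month_before"
        )
        m = Month(2012, 6)
        assert d_budget[m] == pytest.approx(10.0)
        assert d_before[m] == pytest.approx(0.0)

    def test_delta_antisymmetric_in_compared_months(self, timeline):
        series = self._flat_series(Month(2012, 1), Month(2013, 2))
        series[Month(2012, 6)] = 1.62
        deltas = postbudget_delta(series, Month(2012, 3), timeline)
        swap = (series[Month(2012, 3)] - series[Month(2012, 6)]) * 100
        assert deltas[Month(2012, 6)] == pytest.approx(-swap)

    def test_missing_month_is_nan_not_interpolated(self, timeline):
        series = self._flat_series(Month(2012, 1), Month(2013, 2))
        del series[Month(2012, 8)]
        deltas = postbudget_delta(series, Month(2012, 3), timeline)
        assert np.isnan(deltas[Month(2012, 8)])


class TestClassifyShift:
    def test_all_nonnegative_is_full_or_overshift(self):
        s = classify_shift([0.5, 0.2, 3.0, 8.0])
        assert s == ShiftSummary(0.0, 0, 8.0)

    def test_forced_example(self):
        s = classify_shift([-18, -10, -4, +2, +5])
        assert s.depth_pence == -18
        assert s.duration_months == 3
        assert s.end_delta_pence == 5

    def test_tolerance_band(self):
        assert classify_shift([-0.9, -0.5]).duration_months == 0
        assert classify_shift([-1.1, -0.5]).duration_months == 1


class TestRecovery:
    def test_detects_injected_absorption_against_control(self, timeline, cpi):
        def depth_of(absorb):
            sc = single_segment_scenario(absorb, 4, seed=11)
            records, ledger = generate(sc, cpi=cpi)
            series = popular_pack_series(
                records, truth_assignments(ledger), timeline, cpi,
                pack_choice=GRID_CHOICE,
            )
            table = passthrough_table(series, timeline, include_vat_changes=False)
            cyc = table[table["cycle"] == "2012-03"].sort_values("month")
            return classify_shift(cyc["delta_pence"].to_numpy()).depth_pence

        assert depth_of(0.0) == pytest.approx(0.0, abs=1.5)
        assert depth_of(10.0) == pytest.approx(-10.0, abs=2.0)

    def test_overshoot_reaches_target_by_cycle_end(self, timeline, cpi):
        sc = single_segment_scenario(5.0, 2, seed=5, overshoot_pence=10.0)
        records, ledger = generate(sc, cpi=cpi)
        series = popular_pack_series(
            records, truth_assignments(ledger), timeline, cpi,
            pack_choice=GRID_CHOICE,
        )
        table = passthrough_table(series, timeline, include_vat_changes=False)
        cyc = table[table["cycle"] == "2011-03"].sort_values("month")
        s = classify_shift(cyc["delta_pence"].to_numpy())
        assert s.end_delta_pence == pytest.approx(10.0, abs=2.0)

    def test_depth_ordering_matches_graded_absorption(
        self, default_market, timeline, cpi
    ):
        # default market grades absorption deepest in the cheapest
        # segment; recovered depths must preserve that ordering
        scenario, records, ledger = default_market
        series = popular_pack_series(
            records, truth_assignments(ledger), timeline, cpi
        )
        table = passthrough_table(series, timeline)
        depths = {}
        for (ptype, seg), grp in table.groupby(["product_type", "segment"]):
            cyc = grp[grp["cycle"] == "2013-03"].sort_values("month")
            depths[(ptype, seg)] = classify_shift(
                cyc["delta_pence"].to_numpy()
            ).depth_pence
        for ptype in ("FM", "RYO"):
            segs = ["premium", "mid_price", "value"]
            if ptype == "FM":
                segs.append("subvalue")
            vals = [depths[(ptype, s)] for s in segs]
            assert vals == sorted(vals, reverse=True), (ptype, vals)
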