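"""Weighted price, volume, pack-size and price-marking metrics."""
import numpy as np
import pandas as pd
import pytest

from taxshift.errors import UndefinedMetricError
from taxshift.market_data import CpiSeries, SkuMonthRecord, panel_frame
from taxshift.metrics import (
    pack_size_shares,
    postbudget_median_rise,
    price_marking_stats,
    segment_month_metrics,
    segment_stick_price_series,
    volumes_by,
    weighted_avg_real_price,
)
from taxshift.months import Month
from taxshift.synthetic_data import truth_assignments


def rec(sku, month, units, price_pence, ptype="FM", size=20.0, pm=None):
    return SkuMonthRecord(
        sku_id=sku, brand_family=sku, brand_variant=sku, product_type=ptype,
        pack_size=size, multipack=False, price_marked=pm, month=month,
        sales_value_pence=price_pence * units, units_sold=units,
    )


def flat_cpi(months):
    return CpiSeries(index={m: 100.0 for m in months}, base_month=months[0])


class TestWeightedAverage:
    def test_equal_weight_pack_mean(self):
        m = Month(2010, 1)
        cpi = flat_cpi([m])
        records = [rec("a", m, 100, 500), rec("b", m, 100, 1000)]
        assert weighted_avg_real_price(records, cpi) == pytest.approx(7.50)

    def test_stick_basis_brute_force(self):
        m = Month(2010, 1)
        cpi = flat_cpi([m])
        records = [
            rec("a", m, 100, 500, size=20.0),  # 25 p/stick, 2000 sticks
            rec("b", m, 100, 1000, size=10.0),  # 100 p/stick, 1000 sticks
        ]
        expected = (0.25 * 2000 + 1.0 * 1000) / 3000
        got = weighted_avg_real_price(records, cpi, basis="stick")
        assert got == pytest.approx(expected)

    def test_single_sku_identity(self, tiny_cpi):
        m = Month(2010, 2)
        records = [rec("a", m, 7, 653)]
        assert weighted_avg_real_price(records, tiny_cpi) == pytest.approx(
            6.53 * 100 / 110
        )

    def test_empty_slice_is_undefined(self, tiny_cpi):
        with pytest.raises(UndefinedMetricError):
            weighted_avg_real_price([], tiny_cpi)

    def test_within_min_max_and_order_invariant(self, default_market, cpi):
        import random

        _, records, _ = default_market
        sample = [r for r in records if r.month == Month(2013, 5)]
        shuffled = sample[:]
        random.Random(0).shuffle(shuffled)
        v1 = weighted_avg_real_price(sample, cpi)
        v2 = weighted_avg_real_price(shuffled, cpi)
        assert v1 == pytest.approx(v2, rel=1e-12)
        df = panel_frame(sample, cpi=cpi)
        df = df[(df["units"] > 0) & ~df["multipack"]]
        assert df["real_price_gbp"].min() <= v1 <= df["real_price_gbp"].max()

    def test_matches_per_pack_expansion_oracle(self, default_market, cpi):
        rng = np.random.default_rng(0)
        _, records, _ = default_market
        months = sorted({r.month.ordinal for r in records})
        for _ in range(25):
            mo = rng.choice(months)
            ptype = rng.choice(["FM", "RYO"])
            chunk = [
                r for r in records
                if r.month.ordinal == mo and r.product_type == ptype
            ]
            expanded = np.concatenate(
                [
                    np.repeat(
                        (r.sales_value_pence / r.units_sold / 100)
                        * cpi.deflator(r.month),
                        r.units_sold,
                    )
                    for r in chunk
                    if r.units_sold > 0
                ]
            )
            assert weighted_avg_real_price(chunk, cpi) == pytest.approx(
                float(expanded.mean()), rel=1e-9
            )


class TestVolumes:
    def test_empty_group_is_zero_rows(self):
        assert len(volumes_by([])) == 0

    def test_product_types_partition_total(self, default_market):
        _, records, _ = default_market
        total = volumes_by(records).set_index("month_ord")["sticks"]
        by_type = (
            volumes_by(records, by="product_type")
            .groupby("month_ord")["sticks"].sum()
        )
        pd.testing.assert_series_equal(total, by_type, check_names=False)

    def test_segment_totals_match_ledger(self, default_market):
        _, records, ledger = default_market
        labels = truth_assignments(ledger)
        seg = volumes_by(records, by="segment", assignments=labels)
        led = ledger.sku_months.copy()
        led["sticks"] = led["units"] * np.where(
            led["product_type"] == "FM", led["pack_size"], led["pack_size"] / 0.5
        )
        led_tot = led.groupby(["product_type", "segment"])["sticks"].sum()
        seg_tot = seg.groupby(["product_type", "segment"])["sticks"].sum()
        pd.testing.assert_series_equal(seg_tot, led_tot, check_like=True)


class TestPackSizeShares:
    def test_single_size_share_one(self):
        m = Month(2010, 1)
        records = [rec("a", m, 10, 500)]
        labels = pd.DataFrame(
            {"sku_id": ["a"], "product_type": ["FM"], "month_ord": [m.ordinal],
             "segment": ["value"], "source": ["ledger"]}
        )
        from taxshift.segmentation import SegmentAssignments

        shares = pack_size_shares(records, SegmentAssignments(labels))
        assert shares["share"].to_list() == [1.0]

    def test_equal_stick_volumes_split_half(self):
        m = Month(2010, 1)
        records = [
            rec("a", m, 10, 500, size=20.0),   # 200 sticks
            rec("b", m, 20, 300, size=10.0),   # 200 sticks
        ]
        from taxshift.segmentation import SegmentAssignments

        labels = pd.DataFrame(
            {"sku_id": ["a", "b"], "product_type": ["FM", "FM"],
             "month_ord": [m.ordinal] * 2, "segment": ["value"] * 2,
             "source": ["ledger"] * 2}
        )
        shares = pack_size_shares(records, SegmentAssignments(labels))
        assert sorted(shares["share"]) == [0.5, 0.5]

    def test_matches_generator_schedule(self, default_market):
        _, records, ledger = default_market
        scenario = ledger.scenario
        shares = pack_size_shares(records, truth_assignments(ledger))
        for spec in scenario.segments:
            for sched in spec.pack_sizes:
                for year in range(
                    (spec.available_from or scenario.start).year,
                    scenario.end.year + 1,
                ):
                    total = sum(s.share(year) for s in spec.pack_sizes)
                    planted = sched.share(year) / total
                    got = shares[
                        (shares["product_type"] == spec.product_type)
                        & (shares["segment"] == spec.segment)
                        & (shares["year"] == year)
                        & (shares["pack_size"] == sched.size)
                    ]["share"]
                    assert len(got) == 1
                    assert got.iloc[0] == pytest.approx(planted, abs=0.005)

    def test_shares_sum_to_one(self, default_market):
        _, records, ledger = default_market
        shares = pack_size_shares(records, truth_assignments(ledger))
        sums = shares.groupby(["product_type", "segment", "year"])["share"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestPriceMarking:
    def test_before_availability_is_unknown_not_zero(self, default_market, cpi):
        _, records, _ = default_market
        with pytest.raises(UndefinedMetricError):
            price_marking_stats(records, cpi, Month(2011, 7))

    def test_all_pm_gap_undefined(self):
        m = Month(2012, 1)
        cpi = flat_cpi([m])
        records = [rec("a", m, 10, 500, pm=True), rec("b", m, 5, 480, pm=True)]
        stats = price_marking_stats(records, cpi, m)
        assert stats.pct_price_marked == pytest.approx(100.0)
        assert stats.price_gap_pct is None

    def test_recovers_planted_discount(self, default_market, cpi):
        # generator sells PM SKUs at a 5% discount in the FM value
        # band; the gap is measured within one pack size so that the
        # PM/non-PM comparison is not confounded by the 19 vs 20 stick
        # price difference
        _, records, ledger = default_market
        led = ledger.sku_months
        value_skus = set(
            led[(led["segment"] == "value") & (led["product_type"] == "FM")]["sku_id"]
        )
        gaps = []
        for mo in range(Month(2013, 1).ordinal, Month(2014, 1).ordinal):
            chunk = [
                r for r in records
                if r.sku_id in value_skus and r.month.ordinal == mo
                and r.pack_size == 19.0
            ]
            stats = price_marking_stats(chunk, cpi, Month.from_ordinal(mo))
            assert stats.price_gap_pct is not None
            gaps.append(stats.price_gap_pct)
        assert np.mean(gaps) == pytest.approx(-5.0, abs=1.0)


class TestMedianRise:
    def _series(self, values, start=Month(2010, 1), ptype="RYO", seg="premium"):
        return pd.DataFrame(
            {
                "product_type": ptype,
                "segment": seg,
                "month_ord": [start.ordinal + i for i in range(len(values))],
                "stick_price_gbp": values,
            }
        )

    def test_constant_series_all_zero(self, timeline):
        series = self._series([0.2] * 40)
        out = postbudget_median_rise(series, timeline, Month(2011, 3))
        row = out.iloc[0]
        assert row["focus_rise_gbp"] == pytest.approx(0.0)
        assert row["median_other_postbudget_rise_gbp"] == pytest.approx(0.0)
        assert row["median_monthly_rise_gbp"] == pytest.approx(0.0)

    def test_median_of_three_is_middle(self):
        assert float(np.median([0.07, 0.20, 0.19])) == pytest.approx(0.19)

    def test_isolates_planted_postbudget_jump(self, timeline):
        # 0.03 p/month baseline drift, +0.7 p in the month after the
        # 2011 enactment: the comparison shows the jump, the medians
        # stay at the drift
        start = Month(2010, 1)
        n = 48
        drift = 0.0003
        values = []
        level = 0.15
        jump_at = Month(2011, 4).ordinal
        for i in range(n):
            o = start.ordinal + i
            level += 0.007 if o == jump_at else drift
            values.append(level)
        out = postbudget_median_rise(self._series(values), timeline, Month(2011, 3))
        row = out.iloc[0]
        assert row["focus_rise_gbp"] == pytest.approx(0.007, abs=1e-9)
        assert row["median_monthly_rise_gbp"] == pytest.approx(drift, abs=1e-9)
        assert row["median_other_postbudget_rise_gbp"] == pytest.approx(
            drift, abs=1e-9
        )
        assert row["focus_rise_gbp"] > 10 * row["median_monthly_rise_gbp"]


class TestSegmentMonthMetrics:
    def test_table_shape_and_pm_unknown_before_availability(
        self, default_market, cpi, truth_labels
    ):
        _, records, _ = default_market
        table = segment_month_metrics(records, truth_labels, cpi)
        early = table[table["month"] < "2011-08"]
        assert early["pct_price_marked"].isna().all()
        late_cheap = table[
            (table["month"] >= "2012-06")
            & (table["segment"] == "subvalue")
        ]
        assert (late_cheap["pct_price_marked"] > 50).all()
        assert (table["sticks_sold"] > 0).all()
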