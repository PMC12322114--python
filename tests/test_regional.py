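"""Hierarchy and crop-wise disaggregation of regional irrigated area."""

import numpy as np
import pandas as pd
import pytest

from irrigrid.regional import (compute_crop_proportions, compute_region_shares,
                               crop_aai_series, disaggregate_total_aai,
                               unallocated_totals)


def ref_table(rows):
    return pd.DataFrame(rows, columns=["region_id", "crop_code", "aai_ha"])


class TestRegionShares:
    def test_proportional_split(self, region_table):
        ref = ref_table([("N1A", "LMAIZ", 30.0), ("N1B", "LMAIZ", 70.0),
                         ("N2A", "LMAIZ", 1.0), ("N2B", "LMAIZ", 1.0)])
        shares = compute_region_shares(ref, region_table).set_index("region_id")
        assert shares.loc["N1A", "share_pct"] == pytest.approx(30.0)
        assert shares.loc["N1B", "share_pct"] == pytest.approx(70.0)
        assert not shares.loc["N1A", "flagged"]

    def test_even_split_when_no_reference_data(self):
        regions = pd.DataFrame({
            "region_id": ["N1"] + [f"N1{c}" for c in "ABCD"],
            "parent_id": [""] + ["N1"] * 4,
            "level": ["NUTS1"] + ["NUTS2"] * 4,
        })
        shares = compute_region_shares(ref_table([]), regions)
        assert np.allclose(shares["share_pct"], 25.0)
        assert shares["flagged"].all()

    def test_zero_sum_children_fall_back_to_even_split(self):
        regions = pd.DataFrame({
            "region_id": ["N1", "N1A", "N1B", "N1C"],
            "parent_id": ["", "N1", "N1", "N1"],
            "level": ["NUTS1", "NUTS2", "NUTS2", "NUTS2"],
        })
        ref = ref_table([(r, "LMAIZ", 0.0) for r in ("N1A", "N1B", "N1C")])
        shares = compute_region_shares(ref, regions)
        assert np.allclose(shares["share_pct"], 100.0 / 3.0)
        assert shares["flagged"].all()

    def test_negative_reference_rejected(self, region_table):
        with pytest.raises(ValueError, match="negative"):
            compute_region_shares(ref_table([("N1A", "LMAIZ", -1.0)]),
                                  region_table)

    def test_orphan_nuts2_rejected(self):
        regions = pd.DataFrame({"region_id": ["N1A"], "parent_id": ["NX"],
                                "level": ["NUTS2"]})
        with pytest.raises(ValueError, match="parent"):
            compute_region_shares(ref_table([]), regions)


class TestDisaggregateTotal:
    @pytest.mark.parametrize("parent_total,expected", [
        (100.0, [30.0, 70.0]),
        (0.0, [0.0, 0.0]),
    ])
    def test_split_and_zero_propagation(self, region_table, parent_total,
                                        expected):
        ref = ref_table([("N1A", "LMAIZ", 30.0), ("N1B", "LMAIZ", 70.0),
                         ("N2A", "LMAIZ", 5.0), ("N2B", "LMAIZ", 5.0)])
        shares = compute_region_shares(ref, region_table)
        series = pd.DataFrame({"region_id": ["N1"], "year": [2015],
                               "taai_ha": [parent_total]})
        out = disaggregate_total_aai(series, shares, region_table)
        got = out.set_index("region_id")["taai_ha"]
        assert got["N1A"] == pytest.approx(expected[0])
        assert got["N1B"] == pytest.approx(expected[1])

    def test_even_split_conserves_parent_total(self):
        regions = pd.DataFrame({
            "region_id": ["N1"] + [f"N1{c}" for c in "ABCD"],
            "parent_id": [""] + ["N1"] * 4,
            "level": ["NUTS1"] + ["NUTS2"] * 4,
        })
        shares = compute_region_shares(ref_table([]), regions)
        series = pd.DataFrame({"region_id": ["N1"], "year": [2011],
                               "taai_ha": [123.4]})
        out = disaggregate_total_aai(series, shares, regions)
        assert np.allclose(out["taai_ha"], 30.85)
        assert out["taai_ha"].sum() == pytest.approx(123.4, rel=1e-9)

    def test_nuts2_rows_pass_through(self, region_table):
        ref = ref_table([(r, "LMAIZ", 1.0) for r in ("N1A", "N1B", "N2A", "N2B")])
        shares = compute_region_shares(ref, region_table)
        series = pd.DataFrame({"region_id": ["N2A"], "year": [2012],
                               "taai_ha": [42.0]})
        out = disaggregate_total_aai(series, shares, region_table)
        assert out.to_dict("records") == [
            {"region_id": "N2A", "year": 2012, "taai_ha": 42.0}]

    def test_missing_shares_rejected(self, region_table):
        series = pd.DataFrame({"region_id": ["N1"], "year": [2010],
                               "taai_ha": [1.0]})
        empty = pd.DataFrame(columns=["region_id", "parent_id", "share_pct",
                                      "flagged"])
        with pytest.raises(ValueError, match="shares"):
            disaggregate_total_aai(series, empty, region_table)

    def test_hierarchy_conservation_random(self, region_table):
        rng = np.random.default_rng(3)
        ref = ref_table([(r, c, rng.uniform(0, 50))
                         for r in ("N1A", "N1B", "N2A", "N2B")
                         for c in ("LMAIZ", "PARI")])
        shares = compute_region_shares(ref, region_table)
        series = pd.DataFrame(
            [(p, y, rng.uniform(0, 1000)) for p in ("N1", "N2")
             for y in range(2010, 2021)],
            columns=["region_id", "year", "taai_ha"])
        out = disaggregate_total_aai(series, shares, region_table)
        parent = dict(zip(region_table["region_id"], region_table["parent_id"]))
        out["parent_id"] = out["region_id"].map(parent)
        got = out.groupby(["parent_id", "year"])["taai_ha"].sum()
        want = series.set_index(["region_id", "year"])["taai_ha"]
        for key in want.index:
            assert got[key] == pytest.approx(want[key], rel=1e-9)


class TestCropProportions:
    def test_basic_and_single_crop(self):
        out = compute_crop_proportions(
            ref_table([("R", "LMAIZ", 40.0), ("R", "PARI", 60.0),
                       ("S", "OLIVGR", 5.0)]))
        got = out.set_index(["region_id", "crop_code"])["share_pct"]
        assert got[("R", "LMAIZ")] == pytest.approx(40.0)
        assert got[("R", "PARI")] == pytest.approx(60.0)
        assert got[("S", "OLIVGR")] == pytest.approx(100.0)

    def test_uniform_16_crops(self):
        ref = ref_table([("R", f"C{i}", 1.0) for i in range(16)])
        out = compute_crop_proportions(ref)
        assert np.allclose(out["share_pct"], 6.25)
        assert out["share_pct"].sum() == pytest.approx(100.0, rel=1e-9)

    def test_zero_sum_region_flagged(self):
        out = compute_crop_proportions(
            ref_table([("R", "LMAIZ", 0.0), ("R", "PARI", 0.0)]))
        assert (out["share_pct"] == 0).all()
        assert out["flagged"].all()

    def test_duplicate_rows_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            compute_crop_proportions(
                ref_table([("R", "LMAIZ", 1.0), ("R", "LMAIZ", 2.0)]))


class TestCropSeries:
    def test_share_application_and_conservation(self):
        props = compute_crop_proportions(
            ref_table([("R", "LMAIZ", 50.0), ("R", "PARI", 30.0),
                       ("R", "CERE", 20.0)]))
        series = pd.DataFrame({"region_id": ["R", "R"], "year": [2015, 2016],
                               "taai_ha": [80.0, 10.0]})
        out = crop_aai_series(series, props)
        got = out.set_index(["crop_code", "year"])["aai_ha"]
        assert got[("LMAIZ", 2015)] == pytest.approx(40.0)
        assert got[("LMAIZ", 2016)] == pytest.approx(5.0)
        assert got[("PARI", 2016)] == pytest.approx(3.0)
        assert got[("CERE", 2016)] == pytest.approx(2.0)
        sums = out.groupby("year")["aai_ha"].sum()
        assert sums[2015] == pytest.approx(80.0, rel=1e-9)
        assert sums[2016] == pytest.approx(10.0, rel=1e-9)

    def test_zero_total_gives_zero_crops(self):
        props = compute_crop_proportions(ref_table([("R", "LMAIZ", 5.0)]))
        series = pd.DataFrame({"region_id": ["R"], "year": [2010],
                               "taai_ha": [0.0]})
        out = crop_aai_series(series, props)
        assert (out["aai_ha"] == 0).all()

    def test_time_invariance_of_proportions(self):
        props = compute_crop_proportions(
            ref_table([("R", "LMAIZ", 2.0), ("R", "PARI", 3.0)]))
        series = pd.DataFrame({"region_id": ["R", "R"], "year": [2011, 2019],
                               "taai_ha": [55.0, 55.0]})
        out = crop_aai_series(series, props)
        v11 = out[out["year"] == 2011].set_index("crop_code")["aai_ha"]
        v19 = out[out["year"] == 2019].set_index("crop_code")["aai_ha"]
        assert (v11 == v19).all()

    def test_missing_region_rejected(self):
        props = compute_crop_proportions(ref_table([("R", "LMAIZ", 5.0)]))
        series = pd.DataFrame({"region_id": ["S"], "year": [2010],
                               "taai_ha": [1.0]})
        with pytest.raises(ValueError, match="crop shares"):
            crop_aai_series(series, props)

    def test_unallocated_totals_reported_for_flagged_regions(self):
        props = compute_crop_proportions(
            ref_table([("R", "LMAIZ", 0.0), ("S", "LMAIZ", 4.0)]))
        series = pd.DataFrame({"region_id": ["R", "S"], "year": [2012, 2012],
                               "taai_ha": [7.0, 9.0]})
        out = unallocated_totals(series, props)
        assert out.to_dict("records") == [
            {"region_id": "R", "year": 2012, "unallocated_ha": 7.0}]
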