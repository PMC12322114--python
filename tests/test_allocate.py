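"""Crop-share weighting, zonal calibration, capacity cap, rainfed derivation."""

import numpy as np
import pandas as pd
import pytest

from irrigrid.allocate import (CropGridStack, allocate_aai, apply_cell_cap,
                               calibration, crop_aei, crop_growing_area,
                               derive_rainfed, uaa_grid, zonal_sum)
from irrigrid.grid import GridGeometry, RegionRaster


def stack_of(layers, cell_size=1000.0, kind="aai", year=2010):
    first = np.asarray(next(iter(layers.values())), dtype=float)
    geom = GridGeometry(0.0, first.shape[0] * cell_size, cell_size, *first.shape)
    return CropGridStack({c: np.asarray(v, dtype=float)
                          for c, v in layers.items()}, geom, kind, year)


def two_region_raster(shape, cell_size=1000.0):
    geom = GridGeometry(0.0, shape[0] * cell_size, cell_size, *shape)
    idx = np.zeros(shape, dtype=np.int64)
    idx[:, shape[1] // 2:] = 1
    return RegionRaster(idx, ["RA", "RB"], geom)


class TestGrowingArea:
    def test_weight_capped_at_cell_area(self, grid_factory):
        weight = grid_factory([[120.0, 50.0]], units="percent")
        uaa = uaa_grid(weight)
        assert uaa.values == pytest.approx(np.array([[100.0, 50.0]]))

    def test_share_weighting(self, grid_factory):
        weight = grid_factory([[50.0]], units="percent")
        shares = {"LMAIZ": grid_factory([[0.4]], units="fraction"),
                  "PARI": grid_factory([[0.0]], units="fraction")}
        ga = crop_growing_area(weight, shares)
        assert ga["LMAIZ"] == pytest.approx(np.array([[20.0]]))
        assert ga["PARI"] == pytest.approx(np.array([[0.0]]))

    def test_negative_inputs_rejected(self, grid_factory):
        with pytest.raises(ValueError, match="negative"):
            uaa_grid(grid_factory([[-1.0]], units="percent"))
        with pytest.raises(ValueError, match="negative"):
            crop_growing_area(grid_factory([[50.0]], units="percent"),
                              {"X": grid_factory([[-0.1]], units="fraction")})


class TestCropAei:
    def test_share_times_total(self, grid_factory):
        taei = grid_factory([[50.0, 0.0]])
        shares = {"A": grid_factory([[0.2, 0.9]], units="fraction")}
        aei = crop_aei(shares, taei)
        assert aei["A"] == pytest.approx(np.array([[10.0, 0.0]]))

    def test_crop_sum_bounded_by_total(self, grid_factory):
        taei = grid_factory([[40.0]])
        shares = {"A": grid_factory([[0.5]], units="fraction"),
                  "B": grid_factory([[0.3]], units="fraction")}
        aei = crop_aei(shares, taei)
        assert aei["A"] == pytest.approx(np.array([[20.0]]))
        assert aei["B"] == pytest.approx(np.array([[12.0]]))
        assert float(aei.total()[0, 0]) <= 40.0


class TestZonalSum:
    def test_single_region_equals_grid_sum(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 9, (4, 4))
        geom = GridGeometry(0, 4000, 1000, 4, 4)
        rr = RegionRaster(np.zeros((4, 4), dtype=np.int64), ["R"], geom)
        out = zonal_sum(stack_of({"A": v}), rr)
        assert out["total_ha"].iloc[0] == pytest.approx(v.sum())

    def test_two_region_split_matches_masked_sums(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0, 9, (4, 6))
        rr = two_region_raster((4, 6))
        out = zonal_sum(stack_of({"A": v}), rr).set_index("region_id")
        assert out.loc["RA", "total_ha"] == pytest.approx(v[:, :3].sum())
        assert out.loc["RB", "total_ha"] == pytest.approx(v[:, 3:].sum())

    def test_empty_region_is_zero(self):
        geom = GridGeometry(0, 2000, 1000, 2, 2)
        rr = RegionRaster(np.zeros((2, 2), dtype=np.int64), ["R", "EMPTY"], geom)
        out = zonal_sum(stack_of({"A": np.ones((2, 2))}), rr)
        assert out.set_index("region_id").loc["EMPTY", "total_ha"] == 0.0


class TestCalibration:
    def make(self, target, aei):
        targets = pd.DataFrame({"region_id": ["R"], "crop_code": ["A"],
                                "year": [2010], "aai_ha": [target]})
        regional = pd.DataFrame({"region_id": ["R"], "crop_code": ["A"],
                                 "total_ha": [aei]})
        return calibration(targets, regional).iloc[0]

    @pytest.mark.parametrize("target,aei,coeff", [
        (250.0, 1000.0, 25.0),
        (0.0, 1000.0, 0.0),
        (1200.0, 1000.0, 120.0),   # not clipped at 100 %
    ])
    def test_coefficients(self, target, aei, coeff):
        row = self.make(target, aei)
        assert row["coeff_pct"] == pytest.approx(coeff)
        assert not row["flagged"]

    def test_zero_aei_with_positive_target_flagged(self):
        row = self.make(10.0, 0.0)
        assert row["coeff_pct"] == 0.0
        assert row["flagged"]

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            self.make(-1.0, 10.0)


class TestAllocate:
    def test_regional_coefficient_applied(self):
        aei = stack_of({"A": [[8.0, 4.0]]}, kind="aei")
        geom = aei.geometry
        rr = RegionRaster(np.zeros((1, 2), dtype=np.int64), ["R"], geom)
        calib = pd.DataFrame({"region_id": ["R"], "crop_code": ["A"],
                              "year": [2010], "coeff_pct": [25.0],
                              "regional_aei_ha": [12.0],
                              "regional_target_ha": [3.0], "flagged": [False]})
        out = allocate_aai(aei, calib, rr, 2010)
        assert out["A"] == pytest.approx(np.array([[2.0, 1.0]]))

    def test_zero_coefficient_gives_zero(self):
        aei = stack_of({"A": [[8.0]]}, kind="aei")
        rr = RegionRaster(np.zeros((1, 1), dtype=np.int64), ["R"], aei.geometry)
        calib = pd.DataFrame({"region_id": ["R"], "crop_code": ["A"],
                              "year": [2010], "coeff_pct": [0.0],
                              "regional_aei_ha": [8.0],
                              "regional_target_ha": [0.0], "flagged": [False]})
        assert allocate_aai(aei, calib, rr, 2010)["A"] == pytest.approx(np.array([[0.0]]))

    def test_missing_coefficient_rejected(self):
        aei = stack_of({"A": [[8.0]]}, kind="aei")
        rr = RegionRaster(np.zeros((1, 1), dtype=np.int64), ["R"], aei.geometry)
        calib = pd.DataFrame(columns=["region_id", "crop_code", "year",
                                      "coeff_pct"])
        with pytest.raises(ValueError, match="calibration"):
            allocate_aai(aei, calib, rr, 2010)

    def test_regional_sums_meet_targets(self):
        rng = np.random.default_rng(8)
        rr = two_region_raster((4, 6))
        aei = stack_of({"A": rng.uniform(0, 10, (4, 6)),
                        "B": rng.uniform(0, 10, (4, 6))}, kind="aei")
        regional = zonal_sum(aei, rr)
        targets = pd.DataFrame(
            [(r, c, 2010, rng.uniform(1, 30)) for r in ("RA", "RB")
             for c in ("A", "B")],
            columns=["region_id", "crop_code", "year", "aai_ha"])
        calib = calibration(targets, regional)
        out = allocate_aai(aei, calib, rr, 2010)
        got = zonal_sum(out, rr).set_index(["region_id", "crop_code"])
        for rec in targets.itertuples(index=False):
            assert got.loc[(rec.region_id, rec.crop_code), "total_ha"] == \
                pytest.approx(rec.aai_ha, rel=1e-9)

    def test_monotone_in_targets(self):
        # scaling all regional targets by lambda scales every cell by lambda
        rng = np.random.default_rng(12)
        rr = two_region_raster((2, 4))
        aei = stack_of({"A": rng.uniform(1, 10, (2, 4))}, kind="aei")
        regional = zonal_sum(aei, rr)
        targets = pd.DataFrame(
            [("RA", "A", 2010, 5.0), ("RB", "A", 2010, 9.0)],
            columns=["region_id", "crop_code", "year", "aai_ha"])
        base = allocate_aai(aei, calibration(targets, regional), rr, 2010)
        lam = 1.7
        scaled = targets.assign(aai_ha=targets["aai_ha"] * lam)
        out = allocate_aai(aei, calibration(scaled, regional), rr, 2010)
        assert out["A"] == pytest.approx(lam * base["A"], rel=1e-12)


class TestCellCap:
    def test_over_cap_scaled_to_cap(self):
        stack = stack_of({"A": [[60.0]], "B": [[80.0]]})
        capped, diag = apply_cell_cap(stack, 100.0)
        assert capped["A"][0, 0] == pytest.approx(100.0 * 60 / 140)
        assert capped["B"][0, 0] == pytest.approx(100.0 * 80 / 140)
        assert capped["A"][0, 0] + capped["B"][0, 0] == pytest.approx(100.0)
        assert diag["clipped_ha"].sum() == pytest.approx(40.0)

    def test_under_cap_unchanged(self):
        stack = stack_of({"A": [[30.0]], "B": [[40.0]]})
        capped, diag = apply_cell_cap(stack, 100.0)
        assert capped["A"][0, 0] == 30.0
        assert capped["B"][0, 0] == 40.0
        assert diag["clipped_ha"].sum() == 0.0

    def test_crop_ratios_preserved(self):
        stack = stack_of({"A": [[60.0]], "B": [[80.0]]})
        capped, _ = apply_cell_cap(stack, 100.0)
        assert capped["B"][0, 0] / capped["A"][0, 0] == pytest.approx(80 / 60)

    def test_default_cap_is_cell_area(self):
        stack = stack_of({"A": [[150.0]]})
        capped, _ = apply_cell_cap(stack)          # 1 km cell -> 100 ha
        assert capped["A"][0, 0] == pytest.approx(100.0)

    def test_nonpositive_cap_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            apply_cell_cap(stack_of({"A": [[1.0]]}), 0.0)


class TestRainfed:
    def test_subtraction_and_clamp(self):
        ga = stack_of({"A": [[10.0, 3.0, 5.0]]}, kind="growing_area")
        aai = stack_of({"A": [[4.0, 4.0, 0.0]]})
        rf, final, diag = derive_rainfed(ga, aai)
        assert final["A"] == pytest.approx(np.array([[4.0, 3.0, 0.0]]))
        assert rf["A"] == pytest.approx(np.array([[6.0, 0.0, 5.0]]))
        assert diag["clamped_ha"].sum() == pytest.approx(1.0)

    def test_identity_holds_exactly(self):
        rng = np.random.default_rng(21)
        ga = stack_of({"A": rng.uniform(0, 10, (5, 5))}, kind="growing_area")
        aai = stack_of({"A": rng.uniform(0, 12, (5, 5))})
        rf, final, _ = derive_rainfed(ga, aai)
        assert final["A"] + rf["A"] == pytest.approx(ga["A"], abs=0)
        assert (rf["A"] >= 0).all()
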