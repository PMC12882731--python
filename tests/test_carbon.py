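import numpy as np
import pytest

from greenflux import carbon
from greenflux.carbon import (
    InsufficientDataError,
    TransferMatrix,
    carbon_potential,
    change_stats,
    class_npp_stats,
    conversion_pct,
    extract_wetland_mask,
    load_reference_matrix,
    summarize_carbon,
    transfer_matrix,
)
from greenflux.raster import Grid2D, LANDUSE_CLASSES, LandUseGrid


def lu(codes):
    return LandUseGrid(grid=Grid2D(values=np.asarray(codes, dtype=np.int32)),
                       legend=dict(LANDUSE_CLASSES))


def npp_grid(values, nodata=None):
    return Grid2D(values=np.asarray(values, dtype=float), nodata=nodata)


class TestWetlandMask:
    def test_no_water_gives_empty_mask(self):
        mask = extract_wetland_mask(lu(np.ones((4, 4))))
        assert mask.count == 0

    def test_all_water_gives_full_mask(self):
        mask = extract_wetland_mask(lu(np.full((4, 4), 5)))
        assert mask.count == 16

    def test_mixed_grid_matches_cellwise_oracle(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(1, 7, size=(8, 8))
        mask = extract_wetland_mask(lu(codes), wetland_classes=("water", "barren"))
        for i in range(8):
            for j in range(8):
                assert mask.values[i, j] == (codes[i, j] in (5, 6))

    def test_unknown_class_name_rejected(self):
        with pytest.raises(KeyError):
            extract_wetland_mask(lu(np.ones((4, 4))), wetland_classes=("swamp",))


class TestCarbonPotential:
    def test_linear_in_npp_and_b(self):
        mask = extract_wetland_mask(lu(np.full((3, 3), 5)))
        c1 = carbon_potential(npp_grid(np.full((3, 3), 100.0)), mask, b=0.44)
        np.testing.assert_allclose(c1.grid.values, 44.0)
        c2 = carbon_potential(npp_grid(np.full((3, 3), 200.0)), mask, b=0.44)
        np.testing.assert_allclose(c2.grid.values, 2 * c1.grid.values)
        c3 = carbon_potential(npp_grid(np.full((3, 3), 100.0)), mask, b=0.88)
        np.testing.assert_allclose(c3.grid.values, 2 * c1.grid.values)

    def test_outside_mask_is_nodata(self):
        codes = np.ones((2, 2), dtype=np.int32)
        codes[0, 0] = 5
        cm = carbon_potential(npp_grid(np.full((2, 2), 10.0)),
                              extract_wetland_mask(lu(codes)))
        assert cm.grid.values[0, 0] == pytest.approx(4.4)
        assert np.isnan(cm.grid.values[0, 1])

    def test_zero_npp_gives_zero_carbon(self):
        mask = extract_wetland_mask(lu(np.full((2, 2), 5)))
        cm = carbon_potential(npp_grid(np.zeros((2, 2))), mask)
        np.testing.assert_allclose(cm.grid.values, 0.0)

    def test_summary_over_mask_only(self):
        codes = np.full((2, 3), 5, dtype=np.int32)
        codes[0, 0] = 1
        vals = np.array([[999.0, 10.0, 20.0], [30.0, 40.0, 50.0]])
        cm = carbon_potential(npp_grid(vals), extract_wetland_mask(lu(codes)))
        cmin, cmax, cmean = summarize_carbon(cm)
        masked = np.array([10, 20, 30, 40, 50.0]) * 0.44
        assert cmin == pytest.approx(masked.min())
        assert cmax == pytest.approx(masked.max())
        assert cmean == pytest.approx(masked.mean())

    def test_empty_mask_summary_rejected(self):
        cm = carbon_potential(npp_grid(np.ones((2, 2))),
                              extract_wetland_mask(lu(np.ones((2, 2)))))
        with pytest.raises(InsufficientDataError):
            summarize_carbon(cm)


class TestTransferMatrix:
    def test_identical_epochs_give_diagonal_matrix(self):
        g = lu(np.array([[1, 2], [3, 4]]))
        T = transfer_matrix(g, g, cell_area_km2=2.0)
        off = T.areas - np.diag(np.diag(T.areas))
        assert np.all(off == 0)
        assert T.grand_total == pytest.approx(8.0)

    def test_hand_counted_toy_transitions(self):
        a = lu(np.array([[1, 1, 2], [3, 3, 3], [5, 6, 6]]))
        b = lu(np.array([[1, 4, 2], [3, 1, 3], [5, 6, 1]]))
        T = transfer_matrix(a, b, cell_area_km2=1.0)
        # hand count: 1->1:1, 1->4:1, 2->2:1, 3->3:2, 3->1:1, 5->5:1, 6->6:1, 6->1:1
        assert T.areas[T.index("grassland"), T.index("grassland")] == 1
        assert T.areas[T.index("grassland"), T.index("forest")] == 1
        assert T.areas[T.index("cropland"), T.index("cropland")] == 2
        assert T.areas[T.index("cropland"), T.index("grassland")] == 1
        assert T.areas[T.index("barren"), T.index("grassland")] == 1
        assert T.areas.sum() == 9

    def test_conservation_row_column_grand_total(self, landuse_pair):
        lu1, lu2 = landuse_pair
        T = transfer_matrix(lu1, lu2, cell_area_km2=1.575)
        n = lu1.values.size
        assert T.grand_total == pytest.approx(n * 1.575)
        for code, name in lu1.legend.items():
            i = T.index(name)
            assert T.t1_totals()[i] == pytest.approx(
                (lu1.values == code).sum() * 1.575)
            assert T.t2_totals()[i] == pytest.approx(
                (lu2.values == code).sum() * 1.575)

    def test_csv_roundtrip(self, tmp_path, landuse_pair):
        lu1, lu2 = landuse_pair
        T = transfer_matrix(lu1, lu2, cell_area_km2=1.0)
        p = tmp_path / "T.csv"
        T.to_csv(p)
        back = TransferMatrix.from_csv(p)
        np.testing.assert_allclose(back.areas, T.areas)
        np.testing.assert_allclose(back.t1_totals(), T.t1_totals())

    def test_inconsistent_printed_marginals_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            TransferMatrix(labels=("a", "b"), areas=np.eye(2),
                           marginal_t1=np.array([5.0, 5.0]))


class TestChangeStats:
    def test_diagonal_matrix_has_zero_changes(self):
        T = TransferMatrix(labels=("a", "b"), areas=np.diag([4.0, 6.0]))
        cs = change_stats(T)
        np.testing.assert_allclose(cs.net_change, 0.0)
        np.testing.assert_allclose(cs.pct_change, 0.0)
        assert cs.t1_share_pct.sum() == pytest.approx(100.0)
        assert cs.t2_share_pct.sum() == pytest.approx(100.0)

    def test_absent_class_flagged_not_raised(self):
        T = TransferMatrix(labels=("a", "b"),
                           areas=np.array([[0.0, 0.0], [3.0, 7.0]]))
        cs = change_stats(T)
        assert np.isnan(cs.pct_change[0])
        assert np.isfinite(cs.pct_change[1])

    def test_zero_denominator_conversion_is_nan(self):
        T = TransferMatrix(labels=("a", "b"),
                           areas=np.array([[0.0, 0.0], [3.0, 7.0]]))
        assert np.isnan(conversion_pct(T, "a", "b"))

    def test_zero_off_diagonal_conversion_is_zero(self):
        T = TransferMatrix(labels=("a", "b"), areas=np.diag([4.0, 6.0]))
        assert conversion_pct(T, "a", "b") == 0.0


class TestReferenceMatrix:
    """The packaged published 2020->2030 matrix reproduces its narrative."""

    @pytest.fixture(scope="class")
    def ref(self):
        return load_reference_matrix()

    def test_urban_growth_pct(self, ref):
        cs = change_stats(ref)
        assert round(cs.row("urban")["pct_change"], 2) == 184.30

    def test_forest_net_change_and_rate(self, ref):
        cs = change_stats(ref)
        assert round(cs.row("forest")["net_change"], 2) == 1270.53
        assert round(cs.row("forest")["pct_change"], 2) == 0.43

    def test_grassland_dominance_and_reduction(self, ref):
        cs = change_stats(ref)
        g = cs.row("grassland")
        assert round(g["t1_share_pct"], 2) == 64.39
        assert round(g["t2_share_pct"], 2) == 63.73
        assert round(g["net_change"], 2) == -17920.91
        assert round(-g["pct_change"], 2) == 1.03

    def test_conversion_percentages(self, ref):
        assert round(conversion_pct(ref, "cropland", "forest"), 2) == 1.71
        assert round(conversion_pct(ref, "cropland", "forest",
                                    denom_class="forest"), 2) == 0.42
        assert round(conversion_pct(ref, "grassland", "barren"), 2) == 2.95
        assert round(conversion_pct(ref, "grassland", "forest"), 2) == 0.71
        assert round(conversion_pct(ref, "cropland", "grassland"), 2) == 7.14
        assert round(conversion_pct(ref, "cropland", "grassland",
                                    denom_class="grassland"), 2) == 0.30


class TestClassNppStats:
    def test_constant_years_give_zero_slope(self):
        g = lu(np.ones((4, 4)))
        maps = {y: npp_grid(np.full((4, 4), 50.0)) for y in (2025, 2026, 2027)}
        s = class_npp_stats(maps, g)
        np.testing.assert_allclose(s.rate, 0.0)
        np.testing.assert_allclose(s.mean_npp, 50.0)

    def test_linear_trend_recovered_exactly(self):
        g = lu(np.ones((4, 4)))
        maps = {y: npp_grid(np.full((4, 4), 100.0 + 5.0 * (y - 2025)))
                for y in range(2025, 2031)}
        s = class_npp_stats(maps, g)
        assert s.rate[0] == pytest.approx(5.0, abs=1e-9)

    def test_means_match_per_class_averaging(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(1, 4, size=(8, 8))
        g = lu(codes)
        maps = {2025: npp_grid(rng.uniform(0, 300, (8, 8))),
                2026: npp_grid(rng.uniform(0, 300, (8, 8)))}
        s = class_npp_stats(maps, g)
        for k, name in enumerate(s.labels):
            code = g.code_of(name)
            expect = np.mean([maps[y].values[codes == code].mean()
                              for y in (2025, 2026)])
            assert s.mean_npp[k] == pytest.approx(expect)

    def test_absent_class_omitted_with_warning(self):
        g = lu(np.ones((4, 4)))
        with pytest.warns(UserWarning, match="absent"):
            s = class_npp_stats({2025: npp_grid(np.ones((4, 4)))}, g)
        assert s.labels == ("grassland",)
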