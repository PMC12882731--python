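import numpy as np
import pytest

from greenflux import casa
from greenflux.casa import (
    CasaParams,
    ClassBounds,
    annual_npp,
    apar,
    class_ndvi_bounds,
    combine_fpar,
    epsilon,
    fpar_ndvi,
    fpar_sr,
    monthly_npp,
    npp_from_ndvi,
    simple_ratio,
)
from greenflux.raster import Grid2D, LANDUSE_CLASSES, LandUseGrid, MonthStack


def grid(values):
    return Grid2D(values=np.asarray(values, dtype=float))


def uniform_landuse(shape, code=1):
    return LandUseGrid(grid=Grid2D(values=np.full(shape, code, dtype=np.int32)),
                       legend=dict(LANDUSE_CLASSES))


class TestSimpleRatio:
    @pytest.mark.parametrize("ndvi,expect", [(0.0, 1.0), (0.5, 3.0), (-0.5, 1 / 3)])
    def test_closed_form_values(self, ndvi, expect):
        out = simple_ratio(grid([[ndvi]]))
        assert out.values[0, 0] == pytest.approx(expect)

    def test_grid_matches_elementwise_evaluation(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(-0.2, 0.9, size=(6, 6))
        out = simple_ratio(grid(v)).values
        for i in range(6):
            for j in range(6):
                assert out[i, j] == pytest.approx((1 + v[i, j]) / (1 - v[i, j]))

    def test_strictly_increasing_in_ndvi(self):
        v = np.linspace(-0.9, 0.97, 100)
        out = simple_ratio(grid(v[None, :])).values[0]
        assert np.all(np.diff(out) > 0)

    def test_clamp_caps_singularity(self):
        out = simple_ratio(grid([[0.999]]), clamp=0.98)
        assert out.values[0, 0] == pytest.approx((1 + 0.98) / (1 - 0.98))

    def test_unclamped_unit_ndvi_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            simple_ratio(grid([[1.0]]), clamp=None)


class TestClassBounds:
    def test_percentiles_match_sort_based_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 0.9, size=(3, 8, 8))
        stack = MonthStack({(2025, m): grid(vals[m - 1]) for m in (1, 2, 3)})
        lu = uniform_landuse((8, 8), code=4)
        b = class_ndvi_bounds(stack, lu, 5, 95)
        pooled = np.sort(vals.ravel())
        assert b.ndvi_min[4] == pytest.approx(np.percentile(pooled, 5))
        assert b.ndvi_max[4] == pytest.approx(np.percentile(pooled, 95))

    def test_zero_hundred_percentiles_are_min_max(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(size=(8, 8))
        stack = MonthStack({(2025, 1): grid(vals)})
        b = class_ndvi_bounds(stack, uniform_landuse((8, 8)), 0, 100)
        assert b.ndvi_min[1] == vals.min()
        assert b.ndvi_max[1] == vals.max()

    def test_tiny_class_falls_back_to_global_bounds(self):
        codes = np.ones((8, 8), dtype=np.int32)
        codes[0, 0] = 5  # a single water pixel
        lu = LandUseGrid(grid=Grid2D(values=codes))
        rng = np.random.default_rng(3)
        stack = MonthStack({(2025, 1): grid(rng.uniform(size=(8, 8)))})
        with pytest.warns(UserWarning, match="global"):
            b = class_ndvi_bounds(stack, lu)
        assert 5 in b.ndvi_min

    def test_constant_class_bounds_widened(self):
        stack = MonthStack({(2025, 1): grid(np.full((8, 8), 0.4))})
        with pytest.warns(UserWarning, match="degenerate"):
            b = class_ndvi_bounds(stack, uniform_landuse((8, 8)))
        assert b.ndvi_min[1] < 0.4 < b.ndvi_max[1]

    def test_sr_bounds_derived_from_ndvi_bounds(self):
        b = ClassBounds(ndvi_min={1: 0.1}, ndvi_max={1: 0.9})
        assert b.sr_min(1) == pytest.approx(1.1 / 0.9)
        assert b.sr_max(1) == pytest.approx(1.9 / 0.1)


class TestFpar:
    BOUNDS = ClassBounds(ndvi_min={1: 0.1}, ndvi_max={1: 0.9})

    def test_ndvi_min_maps_to_fpar_min(self):
        out = fpar_ndvi(grid([[0.1]]), uniform_landuse((1, 1)), self.BOUNDS)
        assert out.values[0, 0] == pytest.approx(0.001)

    def test_ndvi_max_maps_to_fpar_max(self):
        out = fpar_ndvi(grid([[0.9]]), uniform_landuse((1, 1)), self.BOUNDS)
        assert out.values[0, 0] == pytest.approx(0.95)

    def test_midpoint_linear_rescale(self):
        # 0.001 + (0.4/0.8) * (0.95 - 0.001) = 0.4755
        out = fpar_ndvi(grid([[0.5]]), uniform_landuse((1, 1)), self.BOUNDS)
        assert out.values[0, 0] == pytest.approx(0.4755)

    def test_outside_bounds_clipped(self):
        out = fpar_ndvi(grid([[0.0, 0.99]]), uniform_landuse((1, 2)), self.BOUNDS)
        assert out.values[0, 0] == 0.001
        assert out.values[0, 1] == 0.95

    def test_fpar_sr_endpoints_and_midpoint(self):
        lu = uniform_landuse((1, 3))
        sr_lo, sr_hi = self.BOUNDS.sr_min(1), self.BOUNDS.sr_max(1)
        out = fpar_sr(grid([[sr_lo, sr_hi, 0.5 * (sr_lo + sr_hi)]]), lu, self.BOUNDS)
        assert out.values[0, 0] == pytest.approx(0.001)
        assert out.values[0, 1] == pytest.approx(0.95)
        assert out.values[0, 2] == pytest.approx(0.5 * (0.001 + 0.95))

    def test_missing_class_bounds_raise(self):
        with pytest.raises(KeyError, match="class codes"):
            fpar_ndvi(grid([[0.5]]), uniform_landuse((1, 1), code=4), self.BOUNDS)

    def test_combine_is_equal_weight_mean(self):
        a, b = grid([[0.001]]), grid([[0.95]])
        assert combine_fpar(a, b).values[0, 0] == pytest.approx(0.4755)
        same = grid([[0.3]])
        assert combine_fpar(same, same).values[0, 0] == pytest.approx(0.3)

    def test_combined_fpar_bounded_by_inputs(self):
        rng = np.random.default_rng(4)
        a = grid(rng.uniform(0.001, 0.95, (5, 5)))
        b = grid(rng.uniform(0.001, 0.95, (5, 5)))
        out = combine_fpar(a, b).values
        assert np.all(out >= np.minimum(a.values, b.values) - 1e-15)
        assert np.all(out <= np.maximum(a.values, b.values) + 1e-15)


class TestAparEpsilonNpp:
    def test_apar_product_with_par_fraction(self):
        out = apar(grid([[100.0]]), grid([[0.4]]))
        assert out.values[0, 0] == pytest.approx(20.0)  # 100 * 0.4 * 0.5

    def test_apar_zero_sol_and_linearity(self):
        assert apar(grid([[0.0]]), grid([[0.9]])).values[0, 0] == 0.0
        one = apar(grid([[50.0]]), grid([[0.3]])).values[0, 0]
        two = apar(grid([[100.0]]), grid([[0.3]])).values[0, 0]
        assert two == pytest.approx(2 * one)

    def test_negative_sol_rejected(self):
        with pytest.raises(ValueError):
            apar(grid([[-1.0]]), grid([[0.5]]))

    def test_constant_epsilon_mode(self):
        eps = epsilon(None, None, CasaParams(), template=grid(np.zeros((3, 3))))
        np.testing.assert_allclose(eps.values, 0.389)

    def test_stress_product_bounded(self):
        rng = np.random.default_rng(5)
        t = grid(rng.uniform(-20, 40, (8, 8)))
        w = grid(rng.uniform(0, 0.5, (8, 8)))
        p = CasaParams(epsilon_mode="stress_product")
        eps = epsilon(t, w, p).values
        assert np.all(eps > 0)
        assert np.all(eps <= 1.2 * 1.2 * p.epsilon_max + 1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            CasaParams(epsilon_mode="magic")

    def test_monthly_npp_is_product(self):
        out = monthly_npp(grid([[50.0]]), grid([[0.389]]))
        assert out.values[0, 0] == pytest.approx(19.45)

    def test_monthly_npp_grid_matches_elementwise(self):
        rng = np.random.default_rng(6)
        a, e = rng.uniform(0, 100, (4, 4)), rng.uniform(0.1, 0.5, (4, 4))
        out = monthly_npp(grid(a), grid(e)).values
        np.testing.assert_allclose(out, a * e)


class TestAnnualNpp:
    def test_equal_months_sum_to_twelve_fold(self):
        g = grid(np.full((4, 4), 3.0))
        stack = MonthStack({(2025, m): g for m in range(1, 13)})
        out = annual_npp(stack)
        np.testing.assert_allclose(out.values, 36.0)

    def test_sum_matches_accumulation_loop(self):
        rng = np.random.default_rng(7)
        months = {(2025, m): grid(rng.uniform(0, 30, (4, 4))) for m in range(1, 13)}
        out = annual_npp(MonthStack(months)).values
        acc = np.zeros((4, 4))
        for g in months.values():
            acc += g.values
        np.testing.assert_allclose(out, acc)

    def test_incomplete_year_rejected(self):
        g = grid(np.zeros((4, 4)))
        stack = MonthStack({(2025, m): g for m in range(1, 7)})
        with pytest.raises(ValueError, match="incomplete"):
            annual_npp(stack, 2025)


class TestPipelineInvariants:
    def test_fpar_always_within_stated_endpoints(self, climate, ndvi, landuse_pair):
        _, lu2 = landuse_pair
        bounds = class_ndvi_bounds(ndvi, lu2)
        for key, nd in ndvi.items():
            nd_c = nd.with_values(np.minimum(nd.values, 0.98))
            f1 = fpar_ndvi(nd_c, lu2, bounds)
            f2 = fpar_sr(simple_ratio(nd_c), lu2, bounds)
            fp = combine_fpar(f1, f2).values
            assert fp.min() >= 0.001 - 1e-12
            assert fp.max() <= 0.95 + 1e-12

    def test_saturated_ndvi_constant_sol_closed_form(self):
        """NDVI at the class maximum for all 12 months, constant SOL S:
        annual NPP = 12 * S * 0.95 * 0.5 * epsilon_max exactly."""
        S, p = 400.0, CasaParams()
        nd = grid(np.full((4, 4), 0.8))
        stack = MonthStack({(2025, m): nd for m in range(1, 13)})
        sol = MonthStack({(2025, m): grid(np.full((4, 4), S)) for m in range(1, 13)})
        lu = uniform_landuse((4, 4))
        bounds = ClassBounds(ndvi_min={1: 0.1}, ndvi_max={1: 0.8})
        _, annual, _ = npp_from_ndvi(stack, sol, lu, p, bounds=bounds)
        expect = 12 * S * 0.95 * 0.5 * p.epsilon_max
        np.testing.assert_allclose(annual[2025].values, expect)

    def test_annual_npp_monotone_in_sol_and_ndvi(self, ndvi, climate, landuse_pair):
        _, lu2 = landuse_pair
        sol = climate["solar_radiation"]
        bounds = class_ndvi_bounds(ndvi, lu2)
        _, base, _ = npp_from_ndvi(ndvi, sol, lu2, bounds=bounds)
        # perturb SOL upward
        sol_up = MonthStack({k: g.with_values(g.values * 1.1) for k, g in sol.items()})
        _, up, _ = npp_from_ndvi(ndvi, sol_up, lu2, bounds=bounds)
        assert np.all(up[2025].values >= base[2025].values - 1e-12)
        # perturb NDVI upward (within clip), bounds held fixed
        nd_up = MonthStack({k: g.with_values(np.minimum(g.values + 0.05, 0.95))
                            for k, g in ndvi.items()})
        _, up2, _ = npp_from_ndvi(nd_up, sol, lu2, bounds=bounds)
        assert np.all(up2[2025].values >= base[2025].values - 1e-12)
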