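"""Pearson correlations, model-II regression and the jackknife."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from latgrad import (compare_correlograms, jackknife, model2_fit, pearson_r)
from latgrad.compare import jackknife_se
from latgrad.spatial import Correlogram


def _cg(values):
    values = np.asarray(values, dtype=float)
    k = len(values)
    return Correlogram(table=pd.DataFrame({
        "class_lo_km": np.arange(k) * 100.0,
        "class_hi_km": (np.arange(k) + 1) * 100.0,
        "pairs": np.full(k, 50),
        "moran_i": values,
        "p_value": np.full(k, 0.5),
    }))


class TestPearson:
    def test_affine_relation_is_one(self):
        a = np.array([1.0, 2, 3, 5, 8])
        assert pearson_r(a, 2 * a + 3) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        a = np.array([1.0, 4, 2, 7])
        assert pearson_r(a, -a) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r(np.ones(5), np.arange(5.0))


class TestModel2Fit:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3])
        fit = model2_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_rma_closed_form_example(self):
        fit = model2_fit([0.0, 1, 2], [0.0, 4, 2])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0)

    def test_rma_slope_magnitude_is_sd_ratio(self, rng):
        for _ in range(20):
            x = rng.standard_normal(15)
            y = rng.standard_normal(15) * rng.uniform(0.1, 5)
            fit = model2_fit(x, y)
            assert abs(fit.slope) == pytest.approx(
                np.std(y, ddof=1) / np.std(x, ddof=1), rel=1e-12)

    def test_reciprocal_identity(self, rng):
        x = rng.standard_normal(20)
        y = 0.5 * x + rng.standard_normal(20)
        assert (model2_fit(x, y).slope * model2_fit(y, x).slope
                == pytest.approx(1.0, rel=1e-12))

    def test_ma_equals_rma_for_symmetric_positive_data(self, rng):
        x = rng.standard_normal(50)
        y = x + 0.1 * rng.standard_normal(50)
        y = (y - y.mean()) / np.std(y, ddof=1) * np.std(x, ddof=1)
        rma = model2_fit(x, y, method="rma")
        ma = model2_fit(x, y, method="ma")
        assert rma.slope == pytest.approx(1.0, abs=1e-12)
        assert ma.slope == pytest.approx(1.0, abs=1e-6)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            model2_fit(np.ones(5), np.arange(5.0))

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rma_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        fit = model2_fit(x, y)
        assert abs(fit.slope) == pytest.approx(
            np.std(y, ddof=1) / np.std(x, ddof=1), rel=1e-9)
        assert 0.0 <= fit.r_squared <= 1.0


class TestJackknife:
    def test_collinear_data_zero_se(self):
        x = np.arange(10.0)
        se_slope, se_r2, degen = jackknife(x, 3 * x - 1)
        assert se_slope == pytest.approx(0.0, abs=1e-12)
        assert se_r2 == pytest.approx(0.0, abs=1e-12)
        assert degen == 0

    def test_matches_bruteforce_reimplementation(self, rng):
        x = rng.standard_normal(10)
        y = 0.8 * x + 0.3 * rng.standard_normal(10)
        se_slope, se_r2, _ = jackknife(x, y)
        # independent re-implementation: literal leave-one-out loop
        slopes, r2s = [], []
        for i in range(10):
            xi = np.delete(x, i)
            yi = np.delete(y, i)
            r = np.corrcoef(xi, yi)[0, 1]
            b = np.sign(r) * np.std(yi, ddof=1) / np.std(xi, ddof=1)
            slopes.append(b)
            r2s.append(r * r)
        def se(v):
            v = np.asarray(v)
            return np.sqrt(9 / 10 * np.sum((v - v.mean()) ** 2))
        assert se_slope == pytest.approx(se(slopes), rel=1e-12)
        assert se_r2 == pytest.approx(se(r2s), rel=1e-12)

    def test_duplicated_data_shrinks_se(self, rng):
        x = rng.standard_normal(10)
        y = x + 0.5 * rng.standard_normal(10)
        se10, _, _ = jackknife(x, y)
        se20, _, _ = jackknife(np.tile(x, 2), np.tile(y, 2))
        assert se20 < se10

    def test_se_of_mean_reduces_to_classical_formula(self, rng):
        data = rng.standard_normal(25)
        loo_means = [np.delete(data, i).mean() for i in range(25)]
        classical = np.std(data, ddof=1) / np.sqrt(25)
        assert jackknife_se(loo_means) == pytest.approx(classical, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            jackknife(np.arange(3.0), np.arange(3.0))


class TestCompareCorrelograms:
    def test_identical_correlograms(self, rng):
        vals = rng.uniform(-0.2, 0.8, 10)
        fit = compare_correlograms(_cg(vals), _cg(vals))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.se_slope == pytest.approx(0.0, abs=1e-12)

    def test_doubled_subset_gives_slope_two(self, rng):
        vals = rng.uniform(-0.2, 0.8, 10)
        fit = compare_correlograms(_cg(vals), _cg(2 * vals))
        assert fit.slope == pytest.approx(2.0)

    def test_undefined_classes_dropped_and_counted(self, rng):
        vals = rng.uniform(0, 1, 10)
        sub = vals.copy()
        sub[3] = np.nan
        fit = compare_correlograms(_cg(vals), _cg(sub))
        assert fit.n == 9
        assert fit.n_dropped_classes == 1

    def test_too_few_shared_classes_rejected(self):
        with pytest.raises(ValueError):
            compare_correlograms(_cg([0.1, np.nan, np.nan, 0.2]),
                                 _cg([0.3, 0.1, 0.2, np.nan]))


class TestRichnessSurfaceComparison:
    """Integration: total vs quartile richness when structure is shared.

    When root distance is uncoupled from latitude, the basal and derived
    quartiles are latitude-random subsets of the fauna, so both should
    mirror the total richness surface: positive per-cell correlation and
    correlogram-vs-correlogram model-II slopes near one.  A strongly
    structured scenario (steep gradient, broad ranges) keeps the shared
    signal dominant over subset-specific noise.
    """

    @pytest.fixture(scope="class")
    def surfaces(self):
        from latgrad import (ScenarioConfig, build_grid, correlogram,
                             generate_scenario, match_species, quartile_split,
                             rasterize, richness, root_distances)

        sc = ScenarioConfig(rd_latitude_coupling=0.0, seed=1,
                            richness_gradient=6.0,
                            range_halfwidth_log_mean=2.2)
        tree, ranges, _ = generate_scenario(sc)
        grid = build_grid(sc.bbox)
        pm = rasterize(ranges, grid)
        rd, _ = match_species(root_distances(tree), pm.species)
        basal, derived = quartile_split(rd)
        occ = pm.occupied
        coords = np.column_stack([grid.x_m[occ], grid.y_m[occ]]) / 1000.0
        out = {"total": richness(pm)[occ], "basal": richness(pm, basal)[occ],
               "derived": richness(pm, derived)[occ]}
        cgs = {k: correlogram(v, coords, n_perm=49, seed=1, max_cells=2000)
               for k, v in out.items()}
        return out, cgs

    def test_subset_richness_positively_correlated_with_total(self, surfaces):
        vals, _ = surfaces
        assert pearson_r(vals["total"], vals["basal"]) > 0
        assert pearson_r(vals["total"], vals["derived"]) > 0

    def test_correlogram_slopes_near_one(self, surfaces):
        _, cgs = surfaces
        for subset in ("basal", "derived"):
            fit = compare_correlograms(cgs["total"], cgs[subset])
            assert 0.7 <= fit.slope <= 1.4, subset
            assert fit.r_squared > 0.5
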