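import numpy as np
import pandas as pd
import pytest

from forestvol.geostat import (EmpiricalVariogram, VariogramModel,
                               empirical_semivariogram, fit_variogram,
                               hybrid_fit, hybrid_predict, model_gamma,
                               ok_predict, sill_effect)
from forestvol.learners import DEFAULT_CONFIGS, fit as fit_learner, predict


class TestEmpiricalVariogram:
    def test_two_point_arithmetic(self):
        emp = empirical_semivariogram(
            np.array([[0.0, 0], [1.0, 0], [2.0, 0]]),
            np.array([0.0, 2.0, 0.0]), n_bins=1, max_lag=1.5)
        # two pairs at lag 1 with squared differences 4 and 4
        assert emp.gamma[0] == pytest.approx((4 + 4) / (2 * 2))
        assert emp.counts[0] == 2

    def test_identical_values_zero_everywhere(self, rng):
        locs = rng.uniform(0, 10, (30, 2))
        emp = empirical_semivariogram(locs, np.full(30, 7.0))
        assert np.all(emp.gamma == 0)

    def test_reordering_invariance(self, rng):
        locs = rng.uniform(0, 10, (40, 2))
        vals = rng.normal(size=40)
        emp1 = empirical_semivariogram(locs, vals)
        perm = rng.permutation(40)
        emp2 = empirical_semivariogram(locs[perm], vals[perm])
        np.testing.assert_allclose(emp1.gamma, emp2.gamma)
        np.testing.assert_array_equal(emp1.counts, emp2.counts)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            empirical_semivariogram(np.zeros((5, 2)), np.arange(5.0))


class TestModelGamma:
    def test_spherical_reaches_sill_at_range(self):
        m = VariogramModel("spherical", nugget=0.1, partial_sill=0.9, range_km=30.0)
        assert model_gamma(m, 30.0) == pytest.approx(1.0)
        assert model_gamma(m, 300.0) == pytest.approx(1.0)

    def test_zero_lag_is_zero_for_both_families(self):
        for fam in ("spherical", "gaussian"):
            m = VariogramModel(fam, nugget=5.0, partial_sill=3.0, range_km=2.0)
            assert model_gamma(m, 0.0) == 0.0

    def test_gaussian_effective_range_convention(self):
        m = VariogramModel("gaussian", nugget=0.0, partial_sill=1.0, range_km=1.0)
        assert model_gamma(m, 1.0) == pytest.approx(1 - np.exp(-3.0))

    def test_negative_lag_rejected(self):
        m = VariogramModel("spherical", 0, 1, 1)
        with pytest.raises(ValueError):
            model_gamma(m, -0.5)


class TestSillEffect:
    @pytest.mark.parametrize("nugget,psill,expect", [
        (803.01, 1772.39, 0.31), (1136.22, 4560.93, 0.20), (1975.30, 4668.24, 0.30)])
    def test_reported_residual_models(self, nugget, psill, expect):
        m = VariogramModel("spherical", nugget=nugget, partial_sill=psill,
                           range_km=3.0)
        assert round(sill_effect(m), 2) == expect

    def test_pure_structure_and_pure_nugget(self):
        assert sill_effect(VariogramModel("spherical", 0.0, 5.0, 1.0)) == 0.0
        assert sill_effect(VariogramModel("spherical", 5.0, 0.0, 1.0)) == 1.0

    def test_zero_sill_undefined(self):
        with pytest.raises(ValueError):
            sill_effect(VariogramModel("spherical", 0.0, 0.0, 1.0))


class TestFitVariogram:
    def test_noiseless_roundtrip_within_1pct(self):
        truth = VariogramModel("spherical", nugget=0.1, partial_sill=0.9,
                               range_km=30.0)
        h = np.linspace(2, 60, 15)
        emp = EmpiricalVariogram(h, model_gamma(truth, h), np.full(15, 50))
        fitted = fit_variogram(emp)
        assert fitted.family == "spherical"
        assert fitted.nugget == pytest.approx(0.1, rel=0.01, abs=1e-3)
        assert fitted.partial_sill == pytest.approx(0.9, rel=0.01)
        assert fitted.range_km == pytest.approx(30.0, rel=0.01)

    def test_gaussian_roundtrip(self):
        truth = VariogramModel("gaussian", nugget=0.2, partial_sill=1.3,
                               range_km=4.0)
        h = np.linspace(0.3, 8, 14)
        emp = EmpiricalVariogram(h, model_gamma(truth, h), np.full(14, 40))
        fitted = fit_variogram(emp)
        assert fitted.family == "gaussian"
        assert fitted.sill == pytest.approx(1.5, rel=0.01)
        assert fitted.range_km == pytest.approx(4.0, rel=0.02)

    def test_white_noise_tends_to_pure_nugget(self, rng):
        locs = rng.uniform(0, 100, (300, 2))
        vals = rng.normal(0, 3, 300)
        fitted = fit_variogram(empirical_semivariogram(locs, vals))
        assert fitted.sill_effect > 0.8

    def test_sill_is_nugget_plus_partial_sill(self):
        m = VariogramModel("gaussian", nugget=2.0, partial_sill=7.0, range_km=1.0)
        assert m.sill == 9.0

    def test_too_few_bins_rejected(self):
        emp = EmpiricalVariogram([1.0, 2, 3], [1.0, 1, 1], [5, 5, 5])
        with pytest.raises(ValueError, match="4"):
            fit_variogram(emp)


class TestOrdinaryKriging:
    @pytest.fixture()
    def setting(self, rng):
        locs = rng.uniform(0, 10, (25, 2))
        vals = rng.normal(100, 10, 25)
        model = VariogramModel("spherical", nugget=2.0, partial_sill=8.0,
                               range_km=5.0)
        return model, locs, vals

    def test_exact_at_observations(self, setting):
        model, locs, vals = setting
        preds, _ = ok_predict(model, locs, vals, locs[:5])
        np.testing.assert_allclose(preds, vals[:5], atol=1e-8)

    def test_weights_sum_to_one(self, setting, rng):
        model, locs, vals = setting
        targets = rng.uniform(0, 10, (7, 2))
        _, w = ok_predict(model, locs, vals, targets)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-10)

    def test_pure_nugget_gives_sample_mean(self):
        model = VariogramModel("spherical", nugget=4.0, partial_sill=0.0,
                               range_km=1.0)
        locs = np.array([[0.0, 0], [1, 0], [0, 1]])
        vals = np.array([1.0, 5.0, 9.0])
        preds, w = ok_predict(model, locs, vals, np.array([[3.0, 3.0]]))
        np.testing.assert_allclose(w, 1 / 3, atol=1e-10)
        assert preds[0] == pytest.approx(vals.mean())

    def test_oracle_equivalence_small_n(self):
        # hand-assembled (n+1) linear system solved independently
        model = VariogramModel("spherical", nugget=1.0, partial_sill=3.0,
                               range_km=4.0)
        locs = np.array([[0.0, 0], [2.0, 0], [0.0, 3], [2.0, 2]])
        vals = np.array([10.0, 12.0, 9.0, 14.0])
        target = np.array([[1.0, 1.0]])
        n = 4
        A = np.zeros((n + 1, n + 1))
        for i in range(n):
            for j in range(n):
                A[i, j] = model_gamma(model, np.linalg.norm(locs[i] - locs[j]))
            A[i, n] = A[n, i] = 1.0
        b = np.append([model_gamma(model, np.linalg.norm(locs[i] - target[0]))
                       for i in range(n)], 1.0)
        lam = np.linalg.solve(A, b)[:n]
        preds, w = ok_predict(model, locs, vals, target)
        np.testing.assert_allclose(w[0], lam, atol=1e-10)
        assert preds[0] == pytest.approx(lam @ vals)

    def test_translation_invariance(self, setting, rng):
        model, locs, vals = setting
        targets = rng.uniform(0, 10, (5, 2))
        p1, _ = ok_predict(model, locs, vals, targets)
        shift = np.array([123.4, -77.0])
        p2, _ = ok_predict(model, locs + shift, vals, targets + shift)
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_duplicate_locations_named(self, setting):
        model, locs, vals = setting
        locs2 = locs.copy()
        locs2[3] = locs2[11]
        with pytest.raises(ValueError, match="duplicate"):
            ok_predict(model, locs2, vals, locs2[:1])


class TestHybrid:
    @pytest.fixture()
    def fitted(self, rng):
        n = 40
        X = pd.DataFrame({"a": rng.uniform(0, 10, n), "b": rng.normal(size=n)})
        locs = rng.uniform(0, 5, (n, 2))
        y = 20.0 * X["a"].to_numpy() + rng.normal(0, 5, n)
        base = fit_learner(DEFAULT_CONFIGS["svr"].with_seed(0), X, y)
        return X, y, locs, base

    def test_training_plots_reproduced_exactly(self, fitted):
        X, y, locs, base = fitted
        hm = hybrid_fit(base, X, y, locs)
        pred = hybrid_predict(hm, X, locs)
        np.testing.assert_allclose(pred, y, atol=1e-6)

    def test_additivity_of_kriged_residual(self, fitted, rng):
        X, y, locs, base = fitted
        hm = hybrid_fit(base, X, y, locs)
        targets = rng.uniform(0, 5, (6, 2))
        Xt = pd.DataFrame({"a": rng.uniform(0, 10, 6), "b": rng.normal(size=6)})
        hybrid = hybrid_predict(hm, Xt, targets)
        kriged, _ = ok_predict(hm.variogram, hm.train_locations_km,
                               hm.train_residuals, targets)
        np.testing.assert_allclose(hybrid - predict(base, Xt), kriged, atol=1e-10)

    def test_far_target_saturates_to_global_residual_mean(self, fitted):
        # beyond the range every target sees the same (declustered) weighted
        # mean of the residuals: the kriged surface flattens out
        X, y, locs, base = fitted
        hm = hybrid_fit(base, X, y, locs)
        far = np.array([[1e4, 1e4], [-2e4, 5e3], [3e4, -4e4]])
        kriged, w = ok_predict(hm.variogram, hm.train_locations_km,
                               hm.train_residuals, far)
        np.testing.assert_allclose(kriged, kriged[0], atol=1e-6)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-10)
        r = hm.train_residuals
        assert r.min() - 1e-6 <= kriged[0] <= r.max() + 1e-6

    def test_zero_residuals_degenerate_to_base(self, rng):
        n = 30
        X = pd.DataFrame({"a": np.linspace(0, 1, n)})
        y = np.full(n, 50.0)
        locs = rng.uniform(0, 5, (n, 2))
        base = fit_learner(DEFAULT_CONFIGS["rf"].with_seed(0), X, y)
        hm = hybrid_fit(base, X, y, locs)  # residuals all ~0
        pred = hybrid_predict(hm, X, locs)
        np.testing.assert_allclose(pred, predict(base, X), atol=1e-6)
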