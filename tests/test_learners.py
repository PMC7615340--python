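"""Unit and property tests for the per-arm regression families."""

import numpy as np
import pytest

from carasim import learners as L


class TestPolynomial:
    def test_contains_linear_truth(self):
        x = np.linspace(-5, 5, 12)
        fp = L.fit_polynomial(x, 2 * x + 1, degree=3)
        grid = np.array([-7.0, 0.3, 11.0])
        assert fp.predict(grid[:, None]) == pytest.approx(2 * grid + 1, abs=1e-8)

    def test_exact_quadratic_interpolation(self):
        fp = L.fit_polynomial([-1.0, 0.0, 1.0], [1.0, 0.0, 1.0], degree=2)
        assert fp.predict(2.0) == pytest.approx(4.0, abs=1e-9)

    def test_degree_reduction_on_degenerate_x(self):
        fp = L.fit_polynomial([3.0, 3.0, 3.0], [1.0, 2.0, 3.0], degree=3)
        assert fp.predict(3.0) == pytest.approx(2.0)
        assert fp.predict(-50.0) == pytest.approx(2.0)  # constant fit

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            L.fit_polynomial([], [])


class TestNearestNeighbor:
    def test_k1_nearest_point(self):
        fp = L.fit_nearest_neighbor([0.0, 10.0], [5.0, 7.0], k_neighbors=1)
        assert fp.predict(1.0) == pytest.approx(5.0)

    def test_k2_mean_of_both(self):
        fp = L.fit_nearest_neighbor([0.0, 10.0], [5.0, 7.0], k_neighbors=2)
        assert fp.predict(1.0) == pytest.approx(6.0)

    def test_k_capped_at_dataset_size(self):
        fp3 = L.fit_nearest_neighbor([0.0, 10.0], [5.0, 7.0], k_neighbors=3)
        fp2 = L.fit_nearest_neighbor([0.0, 10.0], [5.0, 7.0], k_neighbors=2)
        assert fp3.predict(4.0) == fp2.predict(4.0)

    def test_distance_ties_include_all_tied_points(self):
        # Neighbours at distance 1 on both sides tie at the k=1 boundary.
        fp = L.fit_nearest_neighbor([-1.0, 1.0, 5.0], [2.0, 4.0, 100.0],
                                    k_neighbors=1)
        assert fp.predict(0.0) == pytest.approx(3.0)

    def test_default_k(self):
        assert L.default_k_neighbors(4) == 3
        assert L.default_k_neighbors(50) == 8


class TestGaussianProcess:
    def test_interpolates_smooth_data(self):
        x = np.linspace(-3, 3, 15)
        y = np.sin(x)
        fp = L.fit_gaussian_process(x, y, seed=0)
        assert fp.predict(x[:, None]) == pytest.approx(y, abs=0.05)

    def test_reverts_to_prior_far_from_data(self):
        x = np.linspace(0, 1, 8)
        y = 5.0 + np.sin(6 * x)
        fp = L.fit_gaussian_process(x, y, seed=0)
        far = fp.predict(1000.0)
        assert far == pytest.approx(np.mean(y), abs=1.0)

    def test_recovers_signal_below_noise_sd(self, rng):
        x = np.linspace(-100, 100, 20)
        noise_sd = 0.1
        y = np.sin(x / 20.0) + noise_sd * rng.standard_normal(20)
        fp = L.fit_gaussian_process(x, y, seed=0)
        grid = np.linspace(-80, 80, 50)
        rmse = np.sqrt(np.mean((fp.predict(grid[:, None]) - np.sin(grid / 20.0)) ** 2))
        assert rmse < noise_sd

    def test_fixed_kernel_refit_matches_hyperparameters(self):
        x = np.linspace(0, 10, 12)
        y = x ** 0.5
        fp = L.fit_gaussian_process(x, y, seed=0)
        fp2 = L.fit_gaussian_process(x, y, seed=0, fixed_kernel=fp.state.kernel_)
        assert fp2.predict(4.0) == pytest.approx(fp.predict(4.0), abs=1e-8)


class TestSpline:
    def test_reproduces_cubic(self):
        x = np.linspace(-10, 10, 25)
        y = 0.01 * x ** 3 - 0.2 * x + 1
        fp = L.fit_spline(x, y)
        interior = np.linspace(-8, 8, 40)
        rmse = np.sqrt(np.mean((fp.predict(interior[:, None])
                                - (0.01 * interior ** 3 - 0.2 * interior + 1)) ** 2))
        assert rmse < 1e-3 * np.ptp(y)

    def test_polynomial_fallback_below_four_points(self):
        fp = L.fit_spline([0.0, 1.0, 2.0], [0.0, 1.0, 4.0])
        assert fp.family == "polynomial"
        assert fp.predict(3.0) == pytest.approx(9.0, abs=1e-8)

    def test_duplicate_x_aggregation(self):
        x = np.r_[np.linspace(0, 10, 10), 5.0, 5.0]
        y = np.r_[np.linspace(0, 10, 10), 4.0, 6.0]
        fp = L.fit_spline(x, y)
        assert np.isfinite(fp.predict(5.0))

    def test_recovers_noisy_slope(self, rng):
        """S2-like heteroscedastic data: predictions within one noise SD of
        the truth on the central 80% of the support."""
        n = 40
        x = rng.uniform(-100, 100, n)
        f = 10 + 0.05 * x
        y = f + 0.1 * np.abs(f) * rng.standard_normal(n)
        fp = L.fit_spline(x, y)
        grid = np.linspace(-80, 80, 30)
        truth = 10 + 0.05 * grid
        sd = 0.1 * np.abs(truth)
        assert np.all(np.abs(fp.predict(grid[:, None]) - truth) < sd)


class TestRandomForest:
    def test_constant_truth(self):
        fp = L.fit_random_forest([1.0, 2.0, 3.0], [7.0, 7.0, 7.0], seed=0)
        assert fp.predict(2.5) == pytest.approx(7.0)

    def test_step_function_recovery(self, rng):
        n = 60
        x = rng.uniform(-100, 100, n)
        truth = np.where(x < -8, 16.0, 9.0)
        y = truth + 0.9 * rng.standard_normal(n)
        fp = L.fit_random_forest(x, y, seed=1)
        lo = np.linspace(-90, -20, 15)
        hi = np.linspace(0, 90, 15)
        assert np.mean(fp.predict(lo[:, None])) == pytest.approx(16.0, abs=0.9)
        assert np.mean(fp.predict(hi[:, None])) == pytest.approx(9.0, abs=0.9)

    def test_seed_reproducibility(self, rng):
        x = rng.uniform(0, 1, 30)
        y = rng.standard_normal(30)
        a = L.fit_random_forest(x, y, seed=7).predict(0.5)
        b = L.fit_random_forest(x, y, seed=7).predict(0.5)
        assert a == b


class TestSurvivalCellwise:
    def test_exponential_mle_all_events(self):
        x = np.tile([1.0, 1.0], (3, 1))
        fp = L.fit_survival_cellwise(x, [10, 20, 30], [1, 1, 1])
        assert fp.predict(np.array([1.0, 1.0])) == pytest.approx(20.0)

    def test_exponential_mle_with_censoring(self):
        x = np.tile([1.0, 1.0], (3, 1))
        fp = L.fit_survival_cellwise(x, [10, 20, 30], [1, 0, 1])
        assert fp.predict(np.array([1.0, 1.0])) == pytest.approx(30.0)  # 60 days / 2 events

    def test_zero_event_cell_uses_pooled_fallback(self):
        x = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
        fp = L.fit_survival_cellwise(x, [10, 30, 50], [1, 1, 0])
        # cell (2,2) has no events -> arm-pooled MLE = 90 / 2
        assert fp.predict(np.array([2.0, 2.0])) == pytest.approx(45.0)
        assert fp.predict(np.array([1.0, 1.0])) == pytest.approx(20.0)

    def test_no_events_anywhere_uses_total_time(self):
        x = np.tile([1.0, 2.0], (2, 1))
        fp = L.fit_survival_cellwise(x, [10, 15], [0, 0])
        assert fp.predict(np.array([1.0, 2.0])) == pytest.approx(25.0)

    def test_closed_form_oracle_on_every_cell(self, rng):
        """Cellwise MLE equals sum(t)/sum(d) computed independently."""
        n = 200
        x = 1 + (rng.random((n, 2)) < 0.5)
        t = np.maximum(np.ceil(rng.exponential(80, n)), 1)
        d = rng.random(n) < 0.7
        fp = L.fit_survival_cellwise(x.astype(float), t, d)
        for a in (1, 2):
            for b in (1, 2):
                cell = (x[:, 0] == a) & (x[:, 1] == b)
                expected = t[cell].sum() / d[cell].sum()
                assert fp.predict(np.array([a, b], dtype=float)) == pytest.approx(expected)

    def test_invariance_to_reordering_and_biomarker_relabeling(self, rng):
        n = 50
        x = 1.0 + (rng.random((n, 2)) < 0.6)
        t = np.maximum(np.ceil(rng.exponential(50, n)), 1)
        d = rng.random(n) < 0.8
        fp = L.fit_survival_cellwise(x, t, d)
        perm = rng.permutation(n)
        fp_perm = L.fit_survival_cellwise(x[perm], t[perm], d[perm])
        fp_swap = L.fit_survival_cellwise(x[:, ::-1], t, d)
        probe = np.array([[1, 1], [1, 2], [2, 1], [2, 2]], dtype=float)
        assert fp_perm.predict(probe) == pytest.approx(fp.predict(probe))
        assert fp_swap.predict(probe[:, ::-1]) == pytest.approx(fp.predict(probe))


class TestSurvivalParametric:
    def test_saturated_equals_cellwise_on_event_data(self, rng):
        n = 80
        x = 1.0 + (rng.random((n, 2)) < 0.5)
        t = np.maximum(np.ceil(rng.exponential(60, n)), 1)
        d = np.ones(n)
        a = L.fit_survival_parametric(x, t, d, "saturated")
        b = L.fit_survival_cellwise(x, t, d)
        probe = np.array([[1, 1], [1, 2], [2, 1], [2, 2]], dtype=float)
        assert a.predict(probe) == pytest.approx(b.predict(probe))

    def test_null_effect_gives_flat_predictions(self, rng):
        n = 400
        x = 1.0 + (rng.random((n, 2)) < 0.5)
        t = np.maximum(np.ceil(rng.exponential(100, n)), 1)
        fp = L.fit_survival_parametric(x, t, np.ones(n), "main_effects")
        probe = np.array([[1, 1], [2, 2]], dtype=float)
        p = fp.predict(probe)
        assert abs(np.log(p[1] / p[0])) < 0.25  # slopes ~ 0

    def test_matches_poisson_glm_cross_check(self, rng):
        """The Newton fit agrees with the equivalent Poisson-offset GLM."""
        sm = pytest.importorskip("statsmodels.api")
        n = 120
        x = 1.0 + (rng.random((n, 2)) < (0.6, 0.8))
        t = np.maximum(np.ceil(rng.exponential(90, n)), 1)
        d = (rng.random(n) < 0.75).astype(float)
        fp = L.fit_survival_parametric(x, t, d, "main_effects")
        Z = np.column_stack([np.ones(n), x - 1.0])
        glm = sm.GLM(d, Z, family=sm.families.Poisson(), offset=np.log(t)).fit()
        assert fp.state == pytest.approx(np.asarray(glm.params), abs=1e-6)

    def test_parameter_recovery_case_study_pattern(self, rng):
        """Saturated fit recovers the (98, 98) vs (141, 189) cell means
        within 15% at 200 patients per arm."""
        n = 200
        x = 1.0 + (rng.random((n, 2)) < (0.6824, 0.8584))
        means = np.where(x[:, 0] == 1, 141.0, 189.0)
        t = np.maximum(np.ceil(rng.exponential(means)), 1)
        d = rng.random(n) > 0.08
        fp = L.fit_survival_parametric(x, t, d, "saturated")
        got1 = fp.predict(np.array([1.0, 2.0]))
        got2 = fp.predict(np.array([2.0, 2.0]))
        assert got1 == pytest.approx(141.0, rel=0.15)
        assert got2 == pytest.approx(189.0, rel=0.15)


class TestFamilyContracts:
    @pytest.mark.parametrize("family", ["polynomial", "nearest", "gp", "spline",
                                        "random_forest"])
    def test_flat_truth_predicts_constant(self, family, rng):
        """Every family fitted on a constant truth predicts that constant."""
        x = rng.uniform(-100, 100, 25)
        y = np.full(25, 42.0)
        fit = L.make_learner(family, "continuous", seed=0)
        fp = fit(x, y)
        grid = np.linspace(-90, 90, 9)
        assert fp.predict(grid[:, None]) == pytest.approx(42.0, abs=1e-4)

    @pytest.mark.parametrize("family", ["cellwise", "main_effects"])
    def test_flat_truth_survival(self, family, rng):
        fit = L.make_learner(family, "survival")
        x = 1.0 + (rng.random((200, 2)) < 0.5)
        t = np.full(200, 60.0)
        fp = fit(x, t, np.ones(200))
        probe = np.array([[1, 1], [2, 2]], dtype=float)
        assert fp.predict(probe) == pytest.approx(60.0, rel=1e-6)

    def test_random_forest_rejected_for_survival(self):
        with pytest.raises(ValueError):
            L.make_learner("random_forest", "survival")

    def test_survival_aliases(self):
        fit = L.make_learner("spline", "survival")
        x = np.array([[1.0, 1.0], [2.0, 2.0]])
        fp = fit(x, np.array([10.0, 30.0]), np.array([1.0, 1.0]))
        assert fp.family == "cellwise"

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            L.make_learner("deep_net", "continuous")
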