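"""Mixture-fitting core: EM correctness, fixed-mean contract, serialization."""

import json

import numpy as np
import pytest
from scipy.integrate import quad

from gmmsort import (
    FitOptions,
    MixtureModel,
    fit_gmm,
    fit_gmm_fixed_means,
    model_density,
    posterior_responsibilities,
)


def monotone(trace, rel=1e-8):
    trace = np.asarray(trace)
    return np.all(np.diff(trace) >= -rel * np.abs(trace[:-1]))


class TestFitGmm:
    def test_single_gaussian_is_sample_moments(self, rng):
        x = rng.normal(0.3, 1.7, 10_000)
        m = fit_gmm(x, 1, FitOptions(seed=0, covariance_floor=0.0))
        assert m.means[0, 0] == pytest.approx(x.mean(), abs=1e-9)
        assert m.covariances[0, 0, 0] == pytest.approx(x.var(), abs=1e-9)

    def test_two_component_recovery(self, rng):
        x = np.concatenate([rng.normal(-4, 1, 2500), rng.normal(4, 1, 2500)])
        m = fit_gmm(x, 2, FitOptions(seed=1))
        mu = np.sort(m.means[:, 0])
        assert mu == pytest.approx([-4.0, 4.0], abs=0.1)
        assert m.weights == pytest.approx([0.5, 0.5], abs=0.05)

    def test_multivariate_recovery(self, rng):
        truth = np.array([[0.0, 0.0], [6.0, 6.0]])
        x = np.vstack([rng.normal(c, 1.0, size=(2500, 2)) for c in truth])
        m = fit_gmm(x, 2, FitOptions(seed=2))
        got = m.means[np.argsort(m.means[:, 0])]
        assert got == pytest.approx(truth, abs=0.1)
        for cov in m.covariances:
            assert np.diag(cov) == pytest.approx([1.0, 1.0], abs=0.1)

    def test_loglik_monotone_every_iteration(self, rng):
        x = np.concatenate([rng.normal(-2, 1, 400), rng.normal(2, 0.5, 400)])
        m = fit_gmm(x, 3, FitOptions(seed=3, n_replicates=3))
        assert monotone(m.loglik_trace)

    def test_best_replicate_selected(self, rng):
        x = np.concatenate([rng.normal(-3, 1, 300), rng.normal(3, 1, 300)])
        m = fit_gmm(x, 2, FitOptions(seed=4, n_replicates=6))
        assert m.log_likelihood == pytest.approx(np.max(m.replicate_logliks))

    def test_reproducible(self, rng):
        x = rng.normal(0, 1, (300, 2))
        a = fit_gmm(x, 3, FitOptions(seed=7))
        b = fit_gmm(x, 3, FitOptions(seed=7))
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.covariances, b.covariances)

    def test_too_few_observations_raises(self):
        with pytest.raises(ValueError, match="at least"):
            fit_gmm(np.arange(3.0), 5)

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit_gmm(np.array([1.0, np.nan, 2.0]), 1)

    def test_identical_observations_degenerate_model(self):
        # constant data: the covariance floor keeps the model well-defined
        x = np.full(50, 2.5)
        m = fit_gmm(x, 1, FitOptions(seed=0))
        assert m.means[0, 0] == pytest.approx(2.5)
        assert m.covariances[0, 0, 0] > 0
        m.validate()

    def test_invariants_hold(self, rng):
        x = rng.normal(0, 1, (400, 3))
        m = fit_gmm(x, 4, FitOptions(seed=5))
        m.validate()
        assert m.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestFixedMeans:
    def test_means_bit_identical(self, rng):
        x = rng.normal(0, 2, (500, 2))
        fixed = np.array([[0.1, -0.2], [1.5, 2.5], [-3.0, 0.0]])
        m = fit_gmm_fixed_means(x, fixed, FitOptions(seed=0))
        assert np.array_equal(m.means, fixed)
        assert m.fixed_means

    def test_recovers_weights_and_variances(self, rng):
        x = np.concatenate([rng.normal(-4, 1.5, 3000), rng.normal(4, 0.5, 1000)])
        m = fit_gmm_fixed_means(x, [[-4.0], [4.0]], FitOptions(seed=1))
        assert m.weights == pytest.approx([0.75, 0.25], abs=0.03)
        assert np.sqrt(m.covariances[:, 0, 0]) == pytest.approx([1.5, 0.5], abs=0.1)
        assert monotone(m.loglik_trace)

    def test_empty_component_clamped_with_warning(self, rng):
        x = rng.normal(0, 0.1, 300)
        with pytest.warns(RuntimeWarning, match="no posterior mass"):
            m = fit_gmm_fixed_means(x, [[0.0], [1000.0]], FitOptions(seed=2))
        assert m.n_components == 2  # never deleted
        assert m.weights[1] < 1e-9
        assert np.array_equal(m.means, [[0.0], [1000.0]])


class TestDensities:
    def test_standard_gaussian_closed_form(self):
        m = MixtureModel(weights=[1.0], means=[[0.0]], covariances=[[[1.0]]])
        assert model_density(m, 0.0)[0] == pytest.approx(1 / np.sqrt(2 * np.pi))

    def test_symmetric_mixture_at_midpoint(self):
        m = MixtureModel(
            weights=[0.5, 0.5], means=[[-1.0], [1.0]], covariances=[[[1.0]], [[1.0]]]
        )
        comp = np.exp(-0.5) / np.sqrt(2 * np.pi)
        assert model_density(m, 0.0)[0] == pytest.approx(comp)

    def test_fitted_density_integrates_to_one(self, rng):
        x = np.concatenate([rng.normal(-2, 0.7, 800), rng.normal(3, 1.3, 800)])
        m = fit_gmm(x, 2, FitOptions(seed=3))
        lo, hi = x.mean() - 10 * x.std(), x.mean() + 10 * x.std()
        integral, _ = quad(lambda v: m.density(v)[0], lo, hi, limit=200)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_dimension_mismatch_raises(self):
        m = MixtureModel(weights=[1.0], means=[[0.0, 0.0]], covariances=[np.eye(2)])
        with pytest.raises(ValueError, match="dimension"):
            model_density(m, np.zeros((4, 3)))


class TestResponsibilities:
    def test_rows_sum_to_one(self, rng):
        x = rng.normal(0, 3, (200, 2))
        m = fit_gmm(x, 4, FitOptions(seed=4))
        r = posterior_responsibilities(m, x)
        assert np.all(r >= 0)
        assert np.abs(r.sum(axis=1) - 1).max() < 1e-12

    def test_point_at_component_mean_dominates(self):
        m = MixtureModel(
            weights=[0.5, 0.5], means=[[-10.0], [10.0]],
            covariances=[[[1.0]], [[1.0]]],
        )
        r = posterior_responsibilities(m, np.array([-10.0]))
        assert r[0, 0] > 0.99

    def test_equidistant_point_splits_evenly(self):
        m = MixtureModel(
            weights=[0.5, 0.5], means=[[-2.0], [2.0]], covariances=[[[1.0]], [[1.0]]]
        )
        r = posterior_responsibilities(m, np.array([0.0]))
        assert r[0] == pytest.approx([0.5, 0.5])

    def test_single_component_all_ones(self, rng):
        m = MixtureModel(weights=[1.0], means=[[0.0]], covariances=[[[1.0]]])
        r = posterior_responsibilities(m, rng.normal(0, 1, 20))
        assert np.all(r == 1.0)


class TestSerialization:
    def test_json_round_trip_bit_exact(self, rng):
        x = rng.normal(0, 1, (300, 2))
        m = fit_gmm(x, 3, FitOptions(seed=6))
        m2 = MixtureModel.from_json(m.to_json())
        assert np.array_equal(m.weights, m2.weights)
        assert np.array_equal(m.means, m2.means)
        assert np.array_equal(m.covariances, m2.covariances)
        assert m.log_likelihood == m2.log_likelihood

    def test_options_validation(self):
        with pytest.raises(ValueError):
            FitOptions(n_replicates=0)
        with pytest.raises(ValueError):
            FitOptions(rel_tol=0)
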