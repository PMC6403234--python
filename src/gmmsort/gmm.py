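"""Gaussian mixture fitting by expectation-maximization.

Provides the standard EM fit with replicate restarts and a "fixed-mean"
variant in which component centers are supplied by the caller and only the
weights and covariances are updated.  The fixed-mean fit is what turns a set
of density peaks into a probabilistic classifier: each retained peak becomes
the immovable center of one Gaussian, and the posterior under the resulting
mixture assigns every observation to a cluster.

Models are plain dataclasses; they serialize to JSON bit-exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from ._em import em_run, em_run_1d

__all__ = [
    "FitOptions",
    "MixtureModel",
    "fit_gmm",
    "fit_gmm_fixed_means",
    "model_density",
    "posterior_responsibilities",
]

_MIN_WEIGHT = 1e-12


@dataclass(frozen=True)
class FitOptions:
    """Options controlling an EM fit.

    n_replicates
        Number of random restarts; the replicate with the highest final
        log-likelihood is returned (default 10).
    max_iterations
        Cap on full E+M cycles (default 10_000).
    rel_tol
        Convergence threshold on the *percentage* change of log p(x)
        between consecutive iterations (default 1e-6, i.e. a relative
        change of 1e-8).
    covariance_floor
        Absolute ridge added to every covariance diagonal each M-step.
        ``None`` (default) uses 1e-6 times the per-dimension data variance.
    seed
        Root seed; replicate r runs on a deterministically spawned child
        stream, so fits are exactly repeatable.
    """

    n_replicates: int = 10
    max_iterations: int = 10_000
    rel_tol: float = 1e-6
    covariance_floor: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")
        if self.covariance_floor is not None and self.covariance_floor < 0:
            raise ValueError("covariance_floor must be >= 0")


@dataclass
class MixtureModel:
    """A fitted Gaussian mixture p(x) = sum_i alpha_i N(x | mu_i, Sigma_i)."""

    weights: np.ndarray  # (k,)
    means: np.ndarray  # (k, d)
    covariances: np.ndarray  # (k, d, d)
    log_likelihood: float = float("nan")
    converged: bool = False
    n_iterations: int = 0
    loglik_trace: np.ndarray | None = None
    fixed_means: bool = False
    replicate_logliks: np.ndarray | None = None
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        if self.means.shape[0] != self.weights.shape[0]:
            self.means = self.means.T
        cov = np.asarray(self.covariances, dtype=float)
        if cov.ndim == 1:  # per-component scalar variances (univariate)
            cov = cov.reshape(-1, 1, 1)
        self.covariances = cov

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    @property
    def stds(self) -> np.ndarray:
        """Per-component standard deviation (univariate models)."""
        if self.dim != 1:
            raise ValueError("stds is defined for univariate models only")
        return np.sqrt(self.covariances[:, 0, 0])

    def validate(self, atol: float = 1e-12) -> None:
        k = self.n_components
        if self.means.shape[0] != k or self.covariances.shape[0] != k:
            raise ValueError("inconsistent component counts")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12 + atol:
            raise ValueError("weights must be non-negative and sum to 1")
        for c in self.covariances:
            if not np.allclose(c, c.T, atol=1e-12):
                raise ValueError("covariance not symmetric")
            np.linalg.cholesky(c)  # raises if not positive definite

    # -- densities ---------------------------------------------------------
    def log_density(self, points: np.ndarray) -> np.ndarray:
        x = _as_2d(points)
        if x.shape[1] != self.dim:
            raise ValueError(
                f"points have dimension {x.shape[1]}, model has {self.dim}"
            )
        return logsumexp(self._log_joint(x), axis=1)

    def density(self, points: np.ndarray) -> np.ndarray:
        return np.exp(self.log_density(points))

    def responsibilities(self, points: np.ndarray) -> np.ndarray:
        x = _as_2d(points)
        if x.shape[1] != self.dim:
            raise ValueError(
                f"points have dimension {x.shape[1]}, model has {self.dim}"
            )
        lj = self._log_joint(x)
        r = np.exp(lj - logsumexp(lj, axis=1, keepdims=True))
        return r / r.sum(axis=1, keepdims=True)

    def _log_joint(self, x: np.ndarray) -> np.ndarray:
        """log(alpha_j) + log N(x | mu_j, Sigma_j), shape (n, k)."""
        n, d = x.shape
        out = np.empty((n, self.n_components))
        with np.errstate(divide="ignore"):
            logw = np.log(self.weights)
        for j in range(self.n_components):
            L = np.linalg.cholesky(self.covariances[j])
            dev = x - self.means[j]
            y = np.linalg.solve(L, dev.T)
            q = np.sum(y * y, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            out[:, j] = logw[j] - 0.5 * (d * np.log(2 * np.pi) + logdet + q)
        return out

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.reshape(self.n_components, -1).tolist(),
            "dim": self.dim,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "fixed_means": self.fixed_means,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        dim = int(d["dim"])
        k = len(d["weights"])
        return cls(
            weights=np.array(d["weights"], dtype=float),
            means=np.array(d["means"], dtype=float).reshape(k, dim),
            covariances=np.array(d["covariances"], dtype=float).reshape(k, dim, dim),
            log_likelihood=d.get("log_likelihood", float("nan")),
            converged=d.get("converged", False),
            n_iterations=d.get("n_iterations", 0),
            fixed_means=d.get("fixed_means", False),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "MixtureModel":
        return cls.from_dict(json.loads(s))


def _as_2d(points: np.ndarray) -> np.ndarray:
    x = np.asarray(points, dtype=float)
    if x.ndim == 0:
        x = x.reshape(1, 1)
    elif x.ndim == 1:
        x = x.reshape(-1, 1)
    return x


def _check_data(data: np.ndarray, k: int) -> np.ndarray:
    x = _as_2d(data)
    if not np.all(np.isfinite(x)):
        raise ValueError("data contains non-finite values")
    if x.shape[0] < k:
        raise ValueError(f"need at least k={k} observations, got {x.shape[0]}")
    return np.ascontiguousarray(x)


def _floor_vector(x: np.ndarray, options: FitOptions) -> np.ndarray:
    if options.covariance_floor is not None:
        return np.full(x.shape[1], float(options.covariance_floor))
    v = np.var(x, axis=0)
    v[v == 0] = 1.0  # degenerate constant column: fall back to absolute ridge
    return 1e-6 * v


def fit_gmm(
    data: np.ndarray, k: int, options: FitOptions | None = None
) -> MixtureModel:
    """Fit a k-component Gaussian mixture by EM with replicate restarts.

    Each replicate initializes means at k distinct observations drawn without
    replacement, covariances at the data covariance, and uniform weights.  The
    replicate with the highest final log-likelihood is returned.
    """
    options = options or FitOptions()
    x = _check_data(data, k)
    n, d = x.shape
    floor = _floor_vector(x, options)
    data_cov = np.cov(x.T).reshape(d, d) + np.diag(floor)
    seeds = np.random.SeedSequence(options.seed).spawn(options.n_replicates)

    best: tuple | None = None
    rep_lls = np.empty(options.n_replicates)
    total_clamped = 0
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        idx = rng.choice(n, size=k, replace=False)
        w = np.full(k, 1.0 / k)
        mu = x[idx].copy()
        cov = np.repeat(data_cov[None], k, axis=0)
        out = _run_replicate(x, w, mu, cov, floor, options, update_means=True)
        rep_lls[r] = out[4]
        total_clamped += out[7]
        if best is None or out[4] > best[4]:
            best = out
    assert best is not None
    w, mu, cov, trace, ll, converged, n_iter, _ = best
    model = MixtureModel(
        weights=w,
        means=mu,
        covariances=cov,
        log_likelihood=ll,
        converged=converged,
        n_iterations=n_iter,
        loglik_trace=trace,
        replicate_logliks=rep_lls,
        n_clamped=total_clamped,
    )
    return model


def fit_gmm_fixed_means(
    data: np.ndarray,
    fixed_means: np.ndarray,
    options: FitOptions | None = None,
) -> MixtureModel:
    """Fit mixture weights and covariances with component means held fixed.

    The returned ``means`` array is bit-identical to ``fixed_means``.  The
    initialization (data covariance, uniform weights) is deterministic, so a
    single EM run suffices regardless of ``n_replicates``.  A component that
    captures no posterior mass is clamped to minimal weight and floor
    covariance (with a warning) instead of being dropped, so component
    indices remain meaningful downstream.
    """
    options = options or FitOptions()
    mu_in = np.atleast_2d(np.asarray(fixed_means, dtype=float))
    if mu_in.size == 0:
        raise ValueError("fixed_means must be non-empty")
    if not np.all(np.isfinite(mu_in)):
        raise ValueError("fixed_means contain non-finite values")
    k = mu_in.shape[0]
    x = _check_data(data, k)
    d = x.shape[1]
    if mu_in.shape[1] != d:
        raise ValueError("fixed_means dimensionality does not match data")
    floor = _floor_vector(x, options)
    data_cov = np.cov(x.T).reshape(d, d) + np.diag(floor)
    w = np.full(k, 1.0 / k)
    mu = mu_in.copy()
    cov = np.repeat(data_cov[None], k, axis=0)
    w, mu_out, cov, trace, ll, converged, n_iter, clamped = _run_replicate(
        x, w, mu, cov, floor, options, update_means=False
    )
    if clamped:
        warnings.warn(
            f"{clamped} component update(s) captured no posterior mass; "
            "weight clamped to minimum and covariance set to the floor",
            RuntimeWarning,
            stacklevel=2,
        )
    model = MixtureModel(
        weights=w,
        means=mu_in.copy(),  # bit-exact contract
        covariances=cov,
        log_likelihood=ll,
        converged=converged,
        n_iterations=n_iter,
        loglik_trace=trace,
        fixed_means=True,
        n_clamped=clamped,
    )
    return model


def _run_replicate(x, w, mu, cov, floor, options, update_means):
    """One EM run; retries with a stronger ridge on Cholesky failure."""
    fl = floor.copy()
    if x.shape[1] == 1:
        # center the data so the fused moment accumulation is well-conditioned
        shift = float(x[:, 0].mean())
        mu1 = np.ascontiguousarray(mu[:, 0]) - shift
        var1 = np.ascontiguousarray(cov[:, 0, 0])
        trace, converged, n_iter, clamped = em_run_1d(
            np.ascontiguousarray(x[:, 0]) - shift,
            w,
            mu1,
            var1,
            float(fl[0]),
            options.max_iterations,
            options.rel_tol,
            update_means,
            _MIN_WEIGHT,
        )
        mu[:, 0] = mu1 + shift
        cov[:, 0, 0] = var1
        return w, mu, cov, trace, float(trace[-1]), converged, n_iter, clamped
    for attempt in range(3):
        try:
            trace, converged, n_iter, clamped = em_run(
                x,
                w,
                mu,
                cov,
                fl,
                options.max_iterations,
                options.rel_tol,
                update_means,
                _MIN_WEIGHT,
            )
            return w, mu, cov, trace, float(trace[-1]), converged, n_iter, clamped
        except np.linalg.LinAlgError:
            if attempt == 2:
                raise
            fl = fl * 1e3 + 1e-12
            cov += np.diag(fl)[None]
    raise AssertionError("unreachable")


def model_density(model: MixtureModel, points: np.ndarray) -> np.ndarray:
    """Mixture density p(x) at the given points."""
    return model.density(points)


def posterior_responsibilities(
    model: MixtureModel, points: np.ndarray
) -> np.ndarray:
    """Per-point, per-component posterior membership probabilities."""
    return model.responsibilities(points)
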