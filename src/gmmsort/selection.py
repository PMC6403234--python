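"""Unsupervised feature selection by mixture-based separability scoring.

Each candidate feature (a PC score or wavelet coefficient) gets a univariate
8-component Gaussian mixture fitted to its empirical distribution, and one of
three scores computed from the fit:

* ``i_peak`` — sum of the mixture density at its local maxima, normalized by
  the highest density; counts the modes a feature can resolve.
* ``i_inf`` — same with inflection points of the density.
* ``i_dist`` — median over all component pairs of
  D_ij = |mu_i - mu_j| * sqrt(alpha_i * alpha_j) / (sigma_i * sigma_j),
  the amplitude-weighted, spread-corrected distance between Gaussians.

A fourth, mixture-free score is the raw feature variance.  Multimodal
features score high; unimodal (noise) features score low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix
from .gmm import FitOptions, MixtureModel, fit_gmm

__all__ = [
    "SeparabilityScore",
    "score_features",
    "peaks_and_inflections",
    "i_peak",
    "i_inf",
    "i_dist",
    "select_top",
    "METRICS",
]

METRICS = ("var", "i_peak", "i_inf", "i_dist")
N_GRID = 100  # discretization of the fitted density over the data range


@dataclass
class SeparabilityScore:
    metric: str
    scores: np.ndarray  # one non-negative score per feature column
    models: list[MixtureModel | None] | None = None
    feature_labels: list[str] | None = None

    def to_frame(self):
        import pandas as pd

        order = np.argsort(-self.scores, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(1, len(order) + 1)
        return pd.DataFrame(
            {
                "feature_id": self.feature_labels
                or [str(i) for i in range(len(self.scores))],
                "metric": self.metric,
                "score": self.scores,
                "rank": rank,
            }
        )


def _grid(data_range) -> np.ndarray:
    lo, hi = float(data_range[0]), float(data_range[1])
    return np.linspace(lo, hi, N_GRID)


def peaks_and_inflections(model: MixtureModel, data_range):
    """Locate density peaks and inflections on a 100-point grid.

    The fitted density is evaluated on 100 equally spaced points spanning the
    data range; peaks are +to- sign changes of the first forward difference
    and inflections are any sign change of the second difference.  A zero
    (plateau) run counts as a single event at its left edge.

    Returns ``(peak_x, inflection_x, grid, pdf)``.
    """
    if model.dim != 1:
        raise ValueError("peak/inflection search is univariate")
    grid = _grid(data_range)
    pdf = model.density(grid)
    peaks = [grid[i] for i in _sign_change_indices(np.diff(pdf), down_only=True)]
    infl = [grid[i] for i in _sign_change_indices(np.diff(pdf, 2), down_only=False)]
    return np.array(peaks), np.array(infl), grid, pdf


def _sign_change_indices(d: np.ndarray, down_only: bool) -> list[int]:
    """Indices (into the parent array) where the sign of d changes.

    For first differences, a +to- change at diff positions (i-1, i) marks a
    local maximum at parent index i; zero runs are treated as a single event
    at their left edge.  For second differences the parent index is offset by
    one so the event sits at the center of the 3-point stencil.
    """
    offset = 0 if down_only else 1
    out: list[int] = []
    prev_sign = 0
    run_start = 0  # parent index where the current sign run would place events
    for i, di in enumerate(d):
        s = 1 if di > 0 else (-1 if di < 0 else 0)
        if s == 0:
            continue
        if prev_sign != 0 and s != prev_sign:
            if not down_only or (prev_sign > 0 and s < 0):
                out.append(run_start + offset)
        prev_sign = s
        run_start = i + 1
    return out


def i_peak(model: MixtureModel, data_range) -> float:
    """Sum of density at its peaks over the max density (grid estimate)."""
    peaks, _, grid, pdf = peaks_and_inflections(model, data_range)
    pmax = pdf.max()
    assert pmax > 0, "fitted density is identically zero on the grid"
    if peaks.size == 0:
        return 0.0
    return float(model.density(peaks).sum() / pmax)


def i_inf(model: MixtureModel, data_range) -> float:
    """Sum of density at its inflection points over the max density."""
    _, infl, grid, pdf = peaks_and_inflections(model, data_range)
    pmax = pdf.max()
    assert pmax > 0, "fitted density is identically zero on the grid"
    if infl.size == 0:
        return 0.0
    return float(model.density(infl).sum() / pmax)


def i_dist(model: MixtureModel) -> float:
    """Median pairwise amplitude-weighted Gaussian distance.

    D_ij = |mu_i - mu_j| sqrt(alpha_i alpha_j) / (sigma_i sigma_j) over all
    unordered component pairs; the score is the median D_ij.
    """
    if model.dim != 1:
        raise ValueError("i_dist is defined for univariate mixtures")
    if model.n_components < 2:
        raise ValueError("i_dist needs at least 2 components")
    mu = model.means[:, 0]
    sigma = model.stds
    ok = sigma > 0
    if not np.all(ok):
        warnings.warn(
            "excluding zero-variance component(s) from i_dist",
            RuntimeWarning,
            stacklevel=2,
        )
        mu, sigma, w = mu[ok], sigma[ok], model.weights[ok]
    else:
        w = model.weights
    if len(mu) < 2:
        return 0.0
    iu, ju = np.triu_indices(len(mu), k=1)
    d = np.abs(mu[iu] - mu[ju]) * np.sqrt(w[iu] * w[ju]) / (sigma[iu] * sigma[ju])
    return float(np.median(d))


def score_features(
    features: FeatureMatrix,
    metric: str,
    options: FitOptions | None = None,
    n_components: int = 8,
    max_points: int = 50_000,
) -> SeparabilityScore:
    """Score every feature column with the chosen separability metric.

    Mixture-based metrics fit an ``n_components``-Gaussian univariate model to
    each column (subsampled to at most ``max_points`` values, seeded from the
    fit options).  A degenerate column (zero variance, or a failed fit) scores
    0 and is never selected.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    x = features.values
    m = x.shape[1]
    scores = np.zeros(m)
    models: list[MixtureModel | None] = [None] * m
    if metric == "var":
        scores[:] = x.var(axis=0, ddof=1)
        return SeparabilityScore(metric, scores, None, features.labels)
    options = options or FitOptions()
    if x.shape[0] < n_components:
        raise ValueError(
            f"need >= {n_components} observations for mixture-based scoring"
        )
    seeds = np.random.SeedSequence(options.seed).spawn(m)
    for c in range(m):
        col = x[:, c]
        if col.std() == 0:
            warnings.warn(
                f"feature column {c} is degenerate; score set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        child_seed = int(seeds[c].generate_state(1)[0] % (2**31))
        sample = col
        if col.shape[0] > max_points:
            rng = np.random.default_rng(seeds[c])
            sample = rng.choice(col, size=max_points, replace=False)
        opts = FitOptions(
            n_replicates=options.n_replicates,
            max_iterations=options.max_iterations,
            rel_tol=options.rel_tol,
            covariance_floor=options.covariance_floor,
            seed=child_seed,
        )
        try:
            model = fit_gmm(sample, n_components, opts)
        except (ValueError, np.linalg.LinAlgError) as exc:  # degenerate fit
            warnings.warn(
                f"mixture fit failed on feature column {c} ({exc}); score 0",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        models[c] = model
        rng_col = (col.min(), col.max())
        if metric == "i_peak":
            scores[c] = i_peak(model, rng_col)
        elif metric == "i_inf":
            scores[c] = i_inf(model, rng_col)
        else:
            scores[c] = i_dist(model)
    return SeparabilityScore(metric, scores, models, features.labels)


def select_top(scores: SeparabilityScore | np.ndarray, n_keep: int = 5) -> np.ndarray:
    """Column indices of the ``n_keep`` highest scores (ties: lower index).

    Zero-score (degenerate) columns are never selected; if fewer than
    ``n_keep`` informative columns exist, all of them are returned with a
    warning.
    """
    s = scores.scores if isinstance(scores, SeparabilityScore) else np.asarray(scores)
    if n_keep > len(s):
        raise ValueError("n_keep exceeds the number of features")
    order = np.argsort(-s, kind="stable")
    eligible = order[s[order] > 0]
    if len(eligible) < n_keep:
        warnings.warn(
            f"only {len(eligible)} informative feature(s) available; keeping all",
            RuntimeWarning,
            stacklevel=2,
        )
        return eligible
    return order[:n_keep]
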