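"""Cluster-count estimation by overclustering + density-peak search, and
fixed-mean mixture classification.

The strategy: fit a deliberately over-parameterized mixture (more Gaussians
than plausible neurons — extra components only smooth the density without
adding modes), locate the modes of the mixture density with a simplex search
started from every component center, merge modes closer than 1% of the data
range, and treat each retained mode as a cluster center.  A fixed-mean
mixture refit at those centers then yields posterior cluster probabilities
for every spike; each spike is assigned to the maximum a posteriori
component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .features import FeatureId
from .gmm import FitOptions, MixtureModel, fit_gmm, fit_gmm_fixed_means

__all__ = [
    "ClusterCenters",
    "SortingResult",
    "overcluster",
    "find_density_peaks",
    "classify",
    "handle_outliers",
    "merge_clusters",
]


@dataclass
class ClusterCenters:
    centers: np.ndarray  # (n_found, d)
    n_found: int
    search_trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.n_found = int(self.n_found)


@dataclass
class SortingResult:
    labels: np.ndarray  # per-spike cluster id, 1-based
    posteriors: np.ndarray  # per-spike max a posteriori probability
    model: MixtureModel  # final fixed-mean mixture
    centers: ClusterCenters
    feature_ids: list[FeatureId] | None = None
    outlier_mask: np.ndarray | None = None  # True where spike was held out of fits

    @property
    def n_clusters(self) -> int:
        return self.centers.n_found

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters + 1)[1:]


def overcluster(
    features: np.ndarray, n_gaussians: int = 12, options: FitOptions | None = None
) -> MixtureModel:
    """Fit a full-covariance mixture with deliberately many components."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[0] < n_gaussians:
        raise ValueError("fewer observations than mixture components")
    return fit_gmm(x, n_gaussians, options)


def find_density_peaks(
    model: MixtureModel,
    data_range: tuple[np.ndarray, np.ndarray],
    merge_tol: float = 0.01,
    merge_mode: str = "joint",
    xatol: float = 1e-4,
    fatol: float = 1e-10,
    max_evaluations: int = 2000,
) -> ClusterCenters:
    """Locate the modes of the mixture density.

    One Nelder-Mead simplex search (on the negative log-density, in
    range-normalized coordinates) starts from each component center.
    Converged endpoints closer than ``merge_tol`` of the data range are
    merged; ``merge_mode='joint'`` uses the Euclidean norm of the
    range-normalized coordinate differences, ``'per_axis'`` merges when every
    axis differs by less than the tolerance.  Each merged group is
    represented by its highest-density endpoint (the actual mode estimate).
    """
    lo = np.asarray(data_range[0], dtype=float)
    hi = np.asarray(data_range[1], dtype=float)
    span = hi - lo
    if not (np.all(np.isfinite(span)) and np.all(span > 0)):
        raise ValueError("data_range must be finite with positive extent")

    # cache per-component precision factors: the search evaluates the density
    # thousands of times on single points
    k, d = model.n_components, model.dim
    precisions = np.stack([np.linalg.inv(c) for c in model.covariances])
    with np.errstate(divide="ignore"):
        const = np.log(model.weights) - 0.5 * (
            d * np.log(2 * np.pi)
            + np.array([np.linalg.slogdet(c)[1] for c in model.covariances])
        )

    def neg_log_density(u: np.ndarray) -> float:
        dev = (lo + u * span) - model.means  # (k, d)
        q = np.einsum("kd,kde,ke->k", dev, precisions, dev)
        lj = const - 0.5 * q
        m = lj.max()
        return -float(m + np.log(np.exp(lj - m).sum()))

    endpoints = []
    trace = []
    for j in range(model.n_components):
        u0 = (model.means[j] - lo) / span
        res = minimize(
            neg_log_density,
            u0,
            method="Nelder-Mead",
            options={
                "xatol": xatol,
                "fatol": fatol,
                "maxfev": max_evaluations,
                "maxiter": max_evaluations,
            },
        )
        rec = {
            "start": model.means[j].copy(),
            "end": lo + res.x * span,
            "log_density": -res.fun,
            "converged": bool(res.success),
            "n_evaluations": int(res.nfev),
        }
        trace.append(rec)
        if not res.success:
            warnings.warn(
                f"peak search from component {j} did not converge; discarded",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        endpoints.append((res.x, -res.fun, j))
    if not endpoints:
        raise RuntimeError("no converged density peaks")
    # merge: greedy by decreasing density
    endpoints.sort(key=lambda e: -e[1])
    kept: list[np.ndarray] = []
    for u, dens, j in endpoints:
        merged = False
        for ku in kept:
            delta = np.abs(u - ku)
            close = (
                np.linalg.norm(delta) < merge_tol
                if merge_mode == "joint"
                else np.all(delta < merge_tol)
            )
            if close:
                merged = True
                break
        if not merged:
            kept.append(u)
    centers = np.array([lo + u * span for u in kept])
    return ClusterCenters(centers=centers, n_found=len(kept), search_trace=trace)


def classify(
    features: np.ndarray,
    centers: ClusterCenters,
    options: FitOptions | None = None,
    feature_ids: list[FeatureId] | None = None,
    core_mask: np.ndarray | None = None,
) -> SortingResult:
    """Fixed-mean mixture classification at the given cluster centers.

    A mixture with means pinned at the centers is fitted (to the core samples
    only, when ``core_mask`` is given), and every spike — including held-out
    outliers — is assigned to the component of highest posterior probability.
    Ties break to the lower cluster index; labels are 1-based.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if centers.n_found == 0:
        raise ValueError("no cluster centers")
    fit_x = x if core_mask is None else x[core_mask]
    model = fit_gmm_fixed_means(fit_x, centers.centers, options)
    resp = model.responsibilities(x)
    labels = np.argmax(resp, axis=1) + 1
    posteriors = resp[np.arange(len(labels)), labels - 1]
    outlier_mask = None if core_mask is None else ~np.asarray(core_mask, dtype=bool)
    return SortingResult(
        labels=labels,
        posteriors=posteriors,
        model=model,
        centers=centers,
        feature_ids=feature_ids,
        outlier_mask=outlier_mask,
    )


def handle_outliers(
    features: np.ndarray,
    k_nn: int = 20,
    cutoff: float | None = None,
) -> np.ndarray:
    """Core-sample mask by k-nearest-neighbor distance.

    A spike is a core sample when its distance to its ``k_nn``-th nearest
    neighbor is below ``cutoff`` (default: twice the 95th percentile of those
    distances).  Non-core spikes should be excluded from the univariate and
    multivariate mixture fits and classified afterwards under the final model
    (template matching by model density) — :func:`classify` does this when
    given the mask.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    n = x.shape[0]
    if not 1 <= k_nn < n:
        raise ValueError("k_nn must be >= 1 and smaller than the spike count")
    tree = cKDTree(x)
    dist, _ = tree.query(x, k=k_nn + 1)
    knn_dist = dist[:, -1]
    if cutoff is None:
        cutoff = 2.0 * np.percentile(knn_dist, 95)
    core = knn_dist <= cutoff
    if core.sum() < 0.5 * n:
        raise ValueError(
            f"outlier cutoff {cutoff:g} excludes more than half the spikes; "
            "this is a misconfiguration"
        )
    return core


def merge_clusters(labels: np.ndarray, merge_ids: list[int], into: int | None = None):
    """Relabel the listed cluster ids into one (explicit, manual merging).

    Returns (new_labels, n_clusters).  Remaining ids are compacted so labels
    stay contiguous from 1.
    """
    labels = np.asarray(labels, dtype=int)
    present = set(np.unique(labels).tolist())
    for m in merge_ids:
        if m not in present:
            raise ValueError(f"cluster id {m} does not exist")
    target = into if into is not None else min(merge_ids)
    out = labels.copy()
    for m in merge_ids:
        out[labels == m] = target
    # compact
    uniq = np.unique(out)
    remap = {old: new for new, old in enumerate(uniq, start=1)}
    out = np.array([remap[v] for v in out])
    return out, len(uniq)
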