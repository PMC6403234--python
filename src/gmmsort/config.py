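"""Pipeline configuration with the standard operating defaults of the framework."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .gmm import FitOptions

__all__ = ["PipelineConfig"]

FEATURE_METHODS = ("pca", "wd", "wpca")
GMM_METRICS = ("i_peak", "i_inf", "i_dist")


@dataclass
class PipelineConfig:
    """End-to-end sorting configuration.

    Defaults follow the standard operating point of the framework: 5 extracted
    features, 8 Gaussians in the univariate separability fits, 12 Gaussians
    in the overclustering step for single-wire recordings (20 for tetrodes),
    10 EM replicates.  The best-performing strategy is weighted PCA of Haar
    coefficients with the pairwise-distance metric (``wpca`` + ``i_dist``).

    The univariate scoring fits run with a capped iteration budget
    (``scoring_max_iterations``) and a subsample cap (``scoring_max_points``):
    separability scores are ranking statistics that stabilize long before the
    likelihood meets the full convergence tolerance, and subsampling the
    scoring fits does not materially change the model.
    """

    feature_method: str = "wpca"
    separability_metric: str = "i_dist"
    n_features: int = 5
    n_overcluster: int | None = None  # None: 12 single-wire, 20 multichannel
    univariate_k: int = 8
    wavelet_levels: int = 4
    fit_options: FitOptions = field(default_factory=FitOptions)
    scoring_max_iterations: int = 200
    scoring_max_points: int = 2000
    merge_tol: float = 0.01
    merge_mode: str = "joint"
    exclude_outliers: bool = False
    outlier_k_nn: int = 20
    # detection options (used when sorting from a raw recording)
    detect_threshold_sd: float = 5.0
    detect_window: int = 64
    detect_polarity: str = "neg"
    detect_lockout_ms: float = 1.0
    bandpass_low: float = 300.0
    bandpass_high: float = 3000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.feature_method not in FEATURE_METHODS:
            raise ValueError(f"feature_method must be one of {FEATURE_METHODS}")
        valid_metrics = GMM_METRICS + ("var",)
        if self.separability_metric not in valid_metrics:
            raise ValueError(f"separability_metric must be one of {valid_metrics}")
        if self.feature_method == "wpca" and self.separability_metric == "var":
            raise ValueError(
                "wpca requires a mixture-based metric: variance weighting would "
                "oppose the z-score normalization"
            )
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")

    def n_overcluster_for(self, n_channels: int) -> int:
        if self.n_overcluster is not None:
            return self.n_overcluster
        return 12 if n_channels <= 1 else 20

    def scoring_options(self, seed: int | None) -> FitOptions:
        fo = self.fit_options
        return FitOptions(
            n_replicates=fo.n_replicates,
            max_iterations=min(fo.max_iterations, self.scoring_max_iterations),
            rel_tol=fo.rel_tol,
            covariance_floor=fo.covariance_floor,
            seed=seed,
        )

    def clustering_options(self, seed: int | None) -> FitOptions:
        fo = self.fit_options
        return FitOptions(
            n_replicates=fo.n_replicates,
            max_iterations=fo.max_iterations,
            rel_tol=fo.rel_tol,
            covariance_floor=fo.covariance_floor,
            seed=seed,
        )

    # -- round-trippable serialization --------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        fo = d.pop("fit_options", None)
        cfg = cls(**d)
        if fo is not None:
            cfg.fit_options = FitOptions(**fo)
        return cfg

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source: str) -> "PipelineConfig":
        import os

        if os.path.exists(source):
            with open(source) as fh:
                return cls.from_dict(json.load(fh))
        return cls.from_dict(json.loads(source))
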