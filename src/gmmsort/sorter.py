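"""The spike-sorting model and its results object.

:class:`SpikeSorter` is built from a :class:`~gmmsort.features.WaveformSet`
(or a raw recording via :meth:`SpikeSorter.from_recording`) plus a
:class:`~gmmsort.config.PipelineConfig`; ``fit()`` runs the full pipeline —
feature extraction, separability scoring, feature selection, overclustering,
density-peak search and fixed-mean classification — and returns a
:class:`SpikeSortingResults` carrying per-spike labels and posteriors, the
final mixture, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import clustering, evaluate, features as feats, selection
from .config import PipelineConfig
from .features import FeatureMatrix, WaveformSet
from .preprocess import RawRecording, bandpass, detect_spikes, match_ground_truth

__all__ = ["SpikeSorter", "SpikeSortingResults"]


class SpikeSorter:
    """GMM-based spike sorter over a set of detected waveforms.

    Parameters
    ----------
    waveforms
        The detected, peak-aligned spike snippets (channels concatenated).
    config
        Pipeline configuration; keyword overrides are applied on top.

    Examples
    --------
    >>> sorter = SpikeSorter(wfs, feature_method="wpca",
    ...                      separability_metric="i_dist")
    >>> res = sorter.fit(seed=7)
    >>> print(res.summary())
    """

    def __init__(
        self,
        waveforms: WaveformSet,
        config: PipelineConfig | None = None,
        **overrides,
    ) -> None:
        if config is None:
            config = PipelineConfig(**overrides)
        elif overrides:
            d = config.to_dict()
            d.update(overrides)
            config = PipelineConfig.from_dict(d)
        self.waveforms = waveforms
        self.config = config

    @classmethod
    def from_recording(
        cls,
        rec: RawRecording,
        config: PipelineConfig | None = None,
        filter_trace: bool = True,
        **overrides,
    ) -> "SpikeSorter":
        """Detect spikes in a raw recording and build a sorter over them.

        Applies the configured band-pass (unless ``filter_trace=False``),
        detects and aligns spikes, and — when the recording carries ground
        truth — labels the detections by 2 ms matching.
        """
        cfg = config or PipelineConfig(**overrides)
        if config is not None and overrides:
            d = cfg.to_dict()
            d.update(overrides)
            cfg = PipelineConfig.from_dict(d)
        if filter_trace:
            rec_f = bandpass(rec, cfg.bandpass_low, cfg.bandpass_high)
        else:
            rec_f = rec
        wfs = detect_spikes(
            rec_f,
            threshold_sd=cfg.detect_threshold_sd,
            window=cfg.detect_window,
            polarity=cfg.detect_polarity,
            lockout_ms=cfg.detect_lockout_ms,
        )
        if rec.ground_truth_times is not None and wfs.n_spikes:
            wfs = match_ground_truth(
                wfs, rec.ground_truth_times, rec.ground_truth_labels
            )
        return cls(wfs, cfg)

    # ------------------------------------------------------------------
    def fit(self, seed: int | None = None) -> "SpikeSortingResults":
        """Run the full pipeline and return the results object.

        ``seed`` overrides the config seed for this run; identical seeds give
        bit-identical results.
        """
        cfg = self.config
        wfs = self.waveforms
        if wfs.n_spikes < 2:
            raise ValueError("need at least 2 spikes to sort")
        root = seed if seed is not None else cfg.seed
        ss = np.random.SeedSequence(root).spawn(3)
        score_seed, cluster_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss[:2]
        )

        candidates, scores, selected = self._extract_and_select(wfs, score_seed)

        x = selected.values
        k_over = cfg.n_overcluster_for(wfs.n_channels)
        core_mask = None
        if cfg.exclude_outliers:
            core_mask = clustering.handle_outliers(x, k_nn=cfg.outlier_k_nn)
        fit_x = x if core_mask is None else x[core_mask]
        over = clustering.overcluster(
            fit_x, k_over, cfg.clustering_options(cluster_seed)
        )
        data_range = (fit_x.min(axis=0), fit_x.max(axis=0))
        centers = clustering.find_density_peaks(
            over, data_range, merge_tol=cfg.merge_tol, merge_mode=cfg.merge_mode
        )
        result = clustering.classify(
            x,
            centers,
            cfg.clustering_options(cluster_seed),
            feature_ids=selected.feature_ids,
            core_mask=core_mask,
        )
        return SpikeSortingResults(
            model=self,
            result=result,
            selected_features=selected,
            candidate_features=candidates,
            scores=scores,
            overcluster_model=over,
            seed=root,
        )

    def _extract_and_select(self, wfs: WaveformSet, score_seed: int):
        cfg = self.config
        metric = cfg.separability_metric
        if cfg.feature_method == "pca":
            candidates = feats.pca_transform(wfs)
        else:
            candidates = feats.haar_wd(wfs, levels=cfg.wavelet_levels)
        if cfg.feature_method == "wpca":
            scores = selection.score_features(
                candidates,
                metric,
                cfg.scoring_options(score_seed),
                n_components=cfg.univariate_k,
                max_points=cfg.scoring_max_points,
            )
            wpcs = feats.weighted_pca(candidates, scores.scores)
            selected = wpcs.select(np.arange(min(cfg.n_features, wpcs.n_features)))
            return candidates, scores, selected
        scores = selection.score_features(
            candidates,
            metric,
            cfg.scoring_options(score_seed),
            n_components=cfg.univariate_k,
            max_points=cfg.scoring_max_points,
        )
        top = selection.select_top(scores, n_keep=min(cfg.n_features, candidates.n_features))
        return candidates, scores, candidates.select(top)


@dataclass
class SpikeSortingResults:
    """Fitted sorting results: labels, posteriors, models and diagnostics."""

    model: SpikeSorter
    result: clustering.SortingResult
    selected_features: FeatureMatrix
    candidate_features: FeatureMatrix
    scores: selection.SeparabilityScore
    overcluster_model: object
    seed: int | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.result.labels

    @property
    def posteriors(self) -> np.ndarray:
        return self.result.posteriors

    @property
    def n_clusters(self) -> int:
        return self.result.n_clusters

    def evaluate(self, true_labels: np.ndarray | None = None) -> dict:
        """MI_norm and error rate against ground truth.

        Uses the waveform set's own labels when none are given; spikes with
        label 0 (background / unmatched detections) are excluded.
        """
        truth = (
            true_labels
            if true_labels is not None
            else self.model.waveforms.true_labels
        )
        if truth is None:
            raise ValueError("no ground-truth labels available")
        truth = np.asarray(truth)
        keep = truth > 0
        table = evaluate.ContingencyTable.from_labels(
            truth[keep], self.labels[keep]
        )
        return {
            "mi_norm": evaluate.mi_norm(table),
            "error_rate": evaluate.error_rate(table),
            "n_clusters": self.n_clusters,
            "n_evaluated": int(keep.sum()),
        }

    def summary(self) -> str:
        """Human-readable overview of the sorting run."""
        cfg = self.model.config
        r = self.result
        sizes = r.cluster_sizes()
        lines = [
            "GMM spike sorting results",
            "=" * 45,
            f"spikes                 {self.model.waveforms.n_spikes}",
            f"feature method         {cfg.feature_method}",
            f"separability metric    {cfg.separability_metric}",
            f"selected features      {', '.join(f.label for f in self.selected_features.feature_ids)}",
            f"overcluster Gaussians  {cfg.n_overcluster_for(self.model.waveforms.n_channels)}",
            f"clusters found         {r.n_clusters}",
            f"mean max posterior     {float(np.mean(r.posteriors)):.4f}",
            f"final log-likelihood   {r.model.log_likelihood:.2f}",
            f"seed                   {self.seed}",
            "-" * 45,
            "cluster   n_spikes   weight",
        ]
        for c in range(r.n_clusters):
            lines.append(
                f"{c + 1:7d}   {sizes[c]:8d}   {r.model.weights[c]:.4f}"
            )
        if self.model.waveforms.true_labels is not None:
            ev = self.evaluate()
            lines += [
                "-" * 45,
                f"MI_norm    {ev['mi_norm']:.2f} %",
                f"error rate {ev['error_rate']:.2f} %",
            ]
        return "\n".join(lines)

    # -- convenience plotting / IO (thin wrappers) -----------------------
    def plot_clusters(self, dims=(0, 1), ax=None):
        from .plots import plot_clusters

        return plot_clusters(self, dims=dims, ax=ax)

    def plot_feature_scores(self, ax=None):
        from .plots import plot_feature_scores

        return plot_feature_scores(self, ax=ax)

    def save(self, prefix: str) -> dict:
        """Write .clu labels, .fet features, model JSON and the config."""
        from . import io as gio

        paths = {
            "clu": gio.write_clu(f"{prefix}.clu", self.labels, self.n_clusters),
            "fet": gio.write_fet(f"{prefix}.fet", self.selected_features),
            "model": gio.write_model_json(f"{prefix}.model.json", self.result),
            "config": f"{prefix}.config.json",
            "labels_csv": gio.write_labels_csv(f"{prefix}.labels.csv", self.labels),
        }
        cfg = self.model.config.to_dict()
        cfg["effective_seed"] = self.seed
        import json

        with open(paths["config"], "w") as fh:
            json.dump(cfg, fh, indent=2)
        return paths
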