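"""Waveform feature extraction: PCA, Haar multiresolution wavelets, weighted PCA.

Three transforms turn a spikes-by-samples waveform matrix into candidate
features:

* ``pca_transform`` — scores on the eigenvectors of the waveform covariance,
  ordered by decreasing eigenvalue.
* ``haar_wd`` — per-channel multiresolution Haar decomposition (orthonormal
  normalization, so the transform conserves energy and is exactly invertible).
* ``weighted_pca`` — z-score each wavelet coefficient, multiply it by a
  separability weight, then apply PCA; this biases the leading components
  toward multimodal (cluster-carrying) coefficients instead of high-variance
  ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "WaveformSet",
    "FeatureId",
    "FeatureMatrix",
    "pca_transform",
    "haar_wd",
    "haar_reconstruct",
    "weighted_pca",
]


@dataclass
class WaveformSet:
    """Spike waveforms: one row per spike, channels concatenated along columns."""

    waveforms: np.ndarray  # (s, n) with n = n_channels * samples_per_channel
    sampling_rate: float
    n_channels: int = 1
    samples_per_channel: int | None = None
    true_labels: np.ndarray | None = None
    spike_times: np.ndarray | None = None  # sample indices in the source trace
    channel_order: tuple[int, ...] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=float))
        if self.samples_per_channel is None:
            if self.waveforms.shape[1] % self.n_channels:
                raise ValueError("waveform length not divisible by n_channels")
            self.samples_per_channel = self.waveforms.shape[1] // self.n_channels
        if self.n_channels * self.samples_per_channel != self.waveforms.shape[1]:
            raise ValueError(
                "n_channels * samples_per_channel must equal waveform length"
            )
        if not np.all(np.isfinite(self.waveforms)):
            raise ValueError("waveforms contain non-finite values")
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=int)
            if len(self.true_labels) != self.n_spikes:
                raise ValueError("true_labels length mismatch")
        if self.spike_times is not None:
            self.spike_times = np.asarray(self.spike_times)
            if len(self.spike_times) != self.n_spikes:
                raise ValueError("spike_times length mismatch")
        if self.channel_order is None:
            self.channel_order = tuple(range(self.n_channels))

    @property
    def n_spikes(self) -> int:
        return self.waveforms.shape[0]

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[1]

    def channel_view(self) -> np.ndarray:
        """Waveforms reshaped to (spikes, channels, samples_per_channel)."""
        return self.waveforms.reshape(
            self.n_spikes, self.n_channels, self.samples_per_channel
        )

    def subset(self, mask_or_idx: np.ndarray) -> "WaveformSet":
        idx = np.asarray(mask_or_idx)
        return WaveformSet(
            waveforms=self.waveforms[idx],
            sampling_rate=self.sampling_rate,
            n_channels=self.n_channels,
            samples_per_channel=self.samples_per_channel,
            true_labels=None if self.true_labels is None else self.true_labels[idx],
            spike_times=None if self.spike_times is None else self.spike_times[idx],
            channel_order=self.channel_order,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class FeatureId:
    """Provenance of one feature column."""

    method: str  # "pca" | "wd" | "wpca"
    index: int | None = None  # component index (pca / wpca)
    scale: int | None = None  # wavelet level j (wd); -j marks the level-j approximation
    shift: int | None = None  # translation k within the level (wd)
    channel: int = 0
    padded: bool = False  # coefficient support includes padding samples

    @property
    def label(self) -> str:
        if self.method in ("pca", "wpca"):
            return f"{self.method}_{self.index}"
        kind = "a" if self.scale < 0 else "d"
        s = f"wd_c{self.channel}_{kind}{abs(self.scale)}_k{self.shift}"
        return s + ("_pad" if self.padded else "")


@dataclass
class FeatureMatrix:
    """Feature values per spike plus per-column provenance."""

    values: np.ndarray  # (s, m)
    feature_ids: list[FeatureId]
    method_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids length must match column count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.feature_ids]

    def select(self, columns: np.ndarray) -> "FeatureMatrix":
        cols = np.asarray(columns, dtype=int)
        return FeatureMatrix(
            values=self.values[:, cols],
            feature_ids=[self.feature_ids[c] for c in cols],
            method_params=dict(self.method_params, selected_from=self.n_features),
        )


def _pca(values: np.ndarray):
    """Eigendecomposition PCA on centered data.

    Returns (scores, loadings, eigenvalues) with components ordered by
    decreasing eigenvalue and each loading's largest-magnitude entry made
    positive for run-to-run determinism.
    """
    if values.shape[0] < 2:
        raise ValueError("PCA needs at least 2 observations")
    mean = values.mean(axis=0)
    xc = values - mean
    cov = xc.T @ xc / (values.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    flip = evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])] < 0
    evecs[:, flip] *= -1.0
    return xc @ evecs, evecs, evals, mean


def pca_transform(wfs: WaveformSet) -> FeatureMatrix:
    """Project waveforms onto principal components of their covariance."""
    scores, loadings, evals, mean = _pca(wfs.waveforms)
    zero_var = int(np.sum(evals <= 1e-12 * max(evals.max(), 1e-300)))
    ids = [FeatureId(method="pca", index=i) for i in range(scores.shape[1])]
    return FeatureMatrix(
        values=scores,
        feature_ids=ids,
        method_params={
            "loadings": loadings,
            "eigenvalues": evals,
            "mean": mean,
            "n_zero_variance": zero_var,
        },
    )


def _pad_length(length: int, levels: int) -> int:
    block = 2**levels
    return ((length + block - 1) // block) * block


def haar_wd(wfs: WaveformSet, levels: int = 4) -> FeatureMatrix:
    """Multiresolution Haar decomposition, per channel, channels concatenated.

    Uses the orthonormal convention (1/sqrt(2) per level), so the map is an
    orthogonal transform: coefficient energy equals sample energy and the
    inverse reconstructs the waveform exactly.  Output per channel holds the
    detail coefficients of levels 1..``levels`` followed by the level-
    ``levels`` approximation — the full n coefficients, no truncation.

    Channels whose length is not divisible by 2**levels are padded at the end
    by symmetric reflection; coefficients whose support touches padded samples
    are kept but flagged in their :class:`FeatureId`.
    """
    spc = wfs.samples_per_channel
    if spc < 2**levels:
        raise ValueError(
            f"samples_per_channel={spc} shorter than 2**levels={2 ** levels}"
        )
    padded_len = _pad_length(spc, levels)
    per_chan = wfs.channel_view()
    cols = []
    ids: list[FeatureId] = []
    for ch in range(wfs.n_channels):
        block = per_chan[:, ch, :]
        if padded_len != spc:
            block = np.pad(block, ((0, 0), (0, padded_len - spc)), mode="symmetric")
        coeffs = pywt.wavedec(block, "haar", mode="periodization", level=levels, axis=1)
        # pywt order: [cA_levels, cD_levels, ..., cD_1] -> emit cD_1..cD_levels, cA
        for j in range(1, levels + 1):
            det = coeffs[levels + 1 - j]
            cols.append(det)
            for kk in range(det.shape[1]):
                pad = (kk + 1) * 2**j > spc
                ids.append(
                    FeatureId(method="wd", scale=j, shift=kk, channel=ch, padded=pad)
                )
        approx = coeffs[0]
        cols.append(approx)
        for kk in range(approx.shape[1]):
            pad = (kk + 1) * 2**levels > spc
            ids.append(
                FeatureId(method="wd", scale=-levels, shift=kk, channel=ch, padded=pad)
            )
    values = np.hstack(cols)
    return FeatureMatrix(
        values=values,
        feature_ids=ids,
        method_params={
            "levels": levels,
            "samples_per_channel": spc,
            "padded_length": padded_len,
            "n_channels": wfs.n_channels,
        },
    )


def haar_reconstruct(fm: FeatureMatrix) -> np.ndarray:
    """Invert :func:`haar_wd`; returns the (s, n) waveform matrix."""
    p = fm.method_params
    levels, spc = p["levels"], p["samples_per_channel"]
    padded_len, n_channels = p["padded_length"], p["n_channels"]
    per_chan_coeffs = padded_len
    out = []
    col = 0
    for _ in range(n_channels):
        block = fm.values[:, col : col + per_chan_coeffs]
        col += per_chan_coeffs
        pieces = []
        pos = 0
        for j in range(1, levels + 1):
            nlen = padded_len // 2**j
            pieces.append(block[:, pos : pos + nlen])
            pos += nlen
        approx = block[:, pos:]
        coeffs = [approx] + pieces[::-1]
        rec = pywt.waverec(coeffs, "haar", mode="periodization", axis=1)
        out.append(rec[:, :spc])
    return np.hstack(out)


def weighted_pca(coeffs: FeatureMatrix, weights: np.ndarray) -> FeatureMatrix:
    """PCA of z-scored coefficients rescaled by separability weights.

    Zero-variance coefficient columns are dropped before z-scoring (they carry
    no information and would divide by zero).  All weights must be finite and
    non-negative; an all-zero weight vector is an error.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != coeffs.n_features:
        raise ValueError("weights length must match coefficient count")
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("weights must be finite and non-negative")
    std = coeffs.values.std(axis=0, ddof=1)
    keep = std > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance coefficient column(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    w = w[keep]
    if not np.any(w > 0):
        raise ValueError("no informative features: all weights are zero")
    vals = coeffs.values[:, keep]
    z = (vals - vals.mean(axis=0)) / std[keep]
    scores, loadings, evals, mean = _pca(z * w)
    ids = [FeatureId(method="wpca", index=i) for i in range(scores.shape[1])]
    return FeatureMatrix(
        values=scores,
        feature_ids=ids,
        method_params={
            "loadings": loadings,
            "eigenvalues": evals,
            "mean": mean,
            "weights": w,
            "kept_columns": np.flatnonzero(keep),
            "source_ids": [coeffs.feature_ids[i] for i in np.flatnonzero(keep)],
        },
    )
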