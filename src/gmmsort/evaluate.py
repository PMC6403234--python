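"""Scoring sorted spikes against ground truth.

The central quantity is the normalized mutual information between true and
assigned labels,

    MI_norm = 100 * MI(X, Y) / H(X),

the percentage of spike-identity information extracted by the sorter.  It is
invariant to relabeling and to splitting a true class across several assigned
clusters (only mixing classes inside one cluster loses information), which
makes it the right score for an overclustering sorter.  The error rate maps
every assigned cluster to its predominant true class and counts mismatches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import WaveformSet

__all__ = [
    "ContingencyTable",
    "mutual_information",
    "mi_norm",
    "error_rate",
    "consistency",
    "symmetry_sweep",
]


@dataclass
class ContingencyTable:
    """Joint counts of true class (rows) by assigned cluster (columns)."""

    counts: np.ndarray
    row_labels: np.ndarray | None = None
    col_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("empty contingency table")

    @classmethod
    def from_labels(cls, truth: np.ndarray, assigned: np.ndarray) -> "ContingencyTable":
        truth = np.asarray(truth)
        assigned = np.asarray(assigned)
        if truth.shape != assigned.shape:
            raise ValueError("label vectors must have equal length")
        rows, ri = np.unique(truth, return_inverse=True)
        cols, ci = np.unique(assigned, return_inverse=True)
        counts = np.zeros((len(rows), len(cols)))
        np.add.at(counts, (ri, ci), 1)
        return cls(counts=counts, row_labels=rows, col_labels=cols)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T, self.col_labels, self.row_labels)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(table: ContingencyTable, miller_madow: bool = False) -> float:
    """Plug-in mutual information in bits; 0*log terms contribute 0.

    ``miller_madow=True`` applies the first-order bias correction
    (K_x + K_y - K_xy - 1) / (2 N ln 2) to the plug-in estimate, where K are
    the numbers of occupied categories.
    """
    pxy = table.counts / table.total
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    mi = _entropy(px) + _entropy(py) - _entropy(pxy.ravel())
    if miller_madow:
        kx = int((px > 0).sum())
        ky = int((py > 0).sum())
        kxy = int((pxy > 0).sum())
        mi += (kx + ky - kxy - 1) / (2.0 * table.total * np.log(2.0))
    return float(mi)


def mi_norm(table: ContingencyTable, miller_madow: bool = False) -> float:
    """Percentage of extracted spike information: 100 * MI(X,Y) / H(X)."""
    px = table.counts.sum(axis=1) / table.total
    hx = _entropy(px)
    if hx <= 0:
        raise ValueError("true-class entropy is zero (single true class)")
    value = 100.0 * mutual_information(table, miller_madow) / hx
    return float(np.clip(value, 0.0, 100.0))


def error_rate(table: ContingencyTable) -> float:
    """Percent of spikes not belonging to their cluster's predominant class.

    Each assigned cluster is identified with its majority true class (ties to
    the lower row index); the error rate is the percentage of spikes whose
    true class differs from their cluster's identity.
    """
    majority = np.argmax(table.counts, axis=0)  # per-column predominant row
    correct = table.counts[majority, np.arange(table.counts.shape[1])].sum()
    return float(100.0 * (1.0 - correct / table.total))


def consistency(
    wfs: WaveformSet,
    config,
    n_runs: int = 25,
    seed: int = 0,
):
    """Re-sort the same waveforms ``n_runs`` times with fresh seeds.

    Reports the mean and variance of MI_norm across runs (the variance is the
    consistency measure: a stable algorithm lands on similar MI_norm values
    regardless of its random initialization) and the mean cluster count.

    Returns ``(summary_dict, per_run_dataframe)``.
    """
    from .sorter import SpikeSorter

    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if wfs.true_labels is None:
        raise ValueError("true labels required")
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n_runs)
    ]
    rows = []
    for r, s in enumerate(seeds):
        res = SpikeSorter(wfs, config).fit(seed=s)
        ev = res.evaluate()
        rows.append(
            {
                "run": r,
                "seed": s,
                "mi_norm": ev["mi_norm"],
                "error_rate": ev["error_rate"],
                "n_clusters": res.result.n_clusters,
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "mean_mi_norm": float(df.mi_norm.mean()),
        "var_mi_norm": float(df.mi_norm.var(ddof=1)),
        "mean_n_clusters": float(df.n_clusters.mean()),
        "n_runs": n_runs,
    }
    return summary, df


def symmetry_sweep(
    wfs: WaveformSet,
    config,
    indexes: np.ndarray | None = None,
    target_classes: list[int] | None = None,
    seed: int = 0,
    min_spikes: int = 10,
):
    """Sorting performance under unbalanced cluster sizes.

    Classes are first equalized in count; one class is then subsampled to
    each symmetry index (percent of the equalized count) and the full
    pipeline is rerun.  For every (class, index) pair the overall MI_norm and
    the MI_norm of the subsampled class against the rest (truth binarized:
    target vs others) are reported.  Indexes leaving fewer than
    ``min_spikes`` spikes are skipped with a warning.
    """
    from .simulate import subsample_for_symmetry
    from .sorter import SpikeSorter

    if wfs.true_labels is None:
        raise ValueError("true labels required")
    classes = np.unique(wfs.true_labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 true classes")
    if indexes is None:
        indexes = np.logspace(0, 2, 8)  # 1% .. 100%
    if target_classes is None:
        target_classes = classes.tolist()
    n_min = min(int(np.sum(wfs.true_labels == c)) for c in classes)
    seeds = np.random.SeedSequence(seed).spawn(len(target_classes) * len(indexes))
    rows = []
    si = 0
    for tc in target_classes:
        for index in indexes:
            ss = seeds[si]
            si += 1
            n_target = int(round(index / 100.0 * n_min))
            if n_target < min_spikes:
                warnings.warn(
                    f"symmetry index {index:.3g}% leaves {n_target} spikes "
                    f"(< {min_spikes}); skipped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            sub_seed = int(ss.generate_state(1)[0] % (2**31))
            sub = subsample_for_symmetry(wfs, tc, index, seed=sub_seed)
            res = SpikeSorter(sub, config).fit(seed=sub_seed)
            overall = mi_norm(
                ContingencyTable.from_labels(sub.true_labels, res.result.labels)
            )
            binary_truth = (sub.true_labels == tc).astype(int)
            smallest = mi_norm(
                ContingencyTable.from_labels(binary_truth, res.result.labels)
            )
            rows.append(
                {
                    "target_class": tc,
                    "symmetry_index": float(index),
                    "mi_norm": overall,
                    "mi_norm_smallest": smallest,
                    "n_clusters": res.result.n_clusters,
                    "n_spikes": sub.n_spikes,
                }
            )
    return pd.DataFrame(rows)
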