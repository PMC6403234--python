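"""File formats: HDF5/CSV waveform containers, flat-binary raw traces,
KlustaKwik-style .fet/.clu text, JSON models and configs."""

from __future__ import annotations

import json
import os

import numpy as np

from .clustering import SortingResult
from .features import FeatureMatrix, WaveformSet
from .gmm import MixtureModel
from .preprocess import RawRecording

__all__ = [
    "save_waveforms_h5",
    "load_waveforms_h5",
    "save_waveforms_csv",
    "load_waveforms_csv",
    "save_recording",
    "load_recording",
    "write_fet",
    "write_clu",
    "read_clu",
    "write_labels_csv",
    "write_model_json",
    "read_model_json",
    "write_features_csv",
]


# -- waveform containers ----------------------------------------------------
def save_waveforms_h5(path: str, wfs: WaveformSet) -> str:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("waveforms", data=wfs.waveforms)
        f.attrs["sampling_rate"] = wfs.sampling_rate
        f.attrs["n_channels"] = wfs.n_channels
        f.attrs["samples_per_channel"] = wfs.samples_per_channel
        f.attrs["channel_order"] = list(wfs.channel_order)
        if wfs.true_labels is not None:
            f.create_dataset("true_labels", data=wfs.true_labels)
        if wfs.spike_times is not None:
            f.create_dataset("spike_times", data=wfs.spike_times)
    return path


def load_waveforms_h5(path: str) -> WaveformSet:
    import h5py

    with h5py.File(path, "r") as f:
        return WaveformSet(
            waveforms=f["waveforms"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            n_channels=int(f.attrs["n_channels"]),
            samples_per_channel=int(f.attrs["samples_per_channel"]),
            channel_order=tuple(int(c) for c in f.attrs["channel_order"]),
            true_labels=f["true_labels"][()] if "true_labels" in f else None,
            spike_times=f["spike_times"][()] if "spike_times" in f else None,
        )


def save_waveforms_csv(path: str, wfs: WaveformSet) -> str:
    """CSV with one spike per row; labels/times, when present, lead."""
    import pandas as pd

    df = pd.DataFrame(wfs.waveforms)
    df.columns = [f"s{i}" for i in range(wfs.n_samples)]
    if wfs.spike_times is not None:
        df.insert(0, "spike_time", wfs.spike_times)
    if wfs.true_labels is not None:
        df.insert(0, "true_label", wfs.true_labels)
    header = (
        f"# sampling_rate={wfs.sampling_rate} n_channels={wfs.n_channels} "
        f"samples_per_channel={wfs.samples_per_channel}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path


def load_waveforms_csv(path: str) -> WaveformSet:
    import pandas as pd

    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
    labels = df.pop("true_label").to_numpy() if "true_label" in df else None
    times = df.pop("spike_time").to_numpy() if "spike_time" in df else None
    return WaveformSet(
        waveforms=df.to_numpy(dtype=float),
        sampling_rate=float(meta["sampling_rate"]),
        n_channels=int(meta["n_channels"]),
        samples_per_channel=int(meta["samples_per_channel"]),
        true_labels=labels,
        spike_times=times,
    )


# -- raw recordings ---------------------------------------------------------
def save_recording(prefix: str, rec: RawRecording, scale: float | None = None) -> dict:
    """Flat binary int16 (channel-interleaved) + JSON sidecar (+ truth CSV)."""
    if scale is None:
        peak = np.abs(rec.traces).max()
        scale = 32000.0 / peak if peak > 0 else 1.0
    data = np.round(rec.traces.T * scale).astype("<i2")  # (samples, channels)
    bin_path = f"{prefix}.bin"
    data.tofile(bin_path)
    sidecar = {
        "n_channels": rec.n_channels,
        "sampling_rate": rec.sampling_rate,
        "dtype": "int16",
        "order": "sample_major",
        "scale": scale,
        "meta": rec.meta,
    }
    json_path = f"{prefix}.json"
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    out = {"bin": bin_path, "json": json_path}
    if rec.ground_truth_times is not None:
        import pandas as pd

        truth_path = f"{prefix}.truth.csv"
        pd.DataFrame(
            {
                "time_sample": rec.ground_truth_times,
                "neuron": (
                    rec.ground_truth_labels
                    if rec.ground_truth_labels is not None
                    else 1
                ),
            }
        ).to_csv(truth_path, index=False)
        out["truth"] = truth_path
    return out


def load_recording(prefix: str) -> RawRecording:
    with open(f"{prefix}.json") as fh:
        sidecar = json.load(fh)
    raw = np.fromfile(f"{prefix}.bin", dtype="<i2")
    nc = sidecar["n_channels"]
    traces = raw.reshape(-1, nc).T.astype(float) / sidecar["scale"]
    truth_times = truth_labels = None
    truth_path = f"{prefix}.truth.csv"
    if os.path.exists(truth_path):
        import pandas as pd

        t = pd.read_csv(truth_path)
        truth_times = t["time_sample"].to_numpy()
        truth_labels = t["neuron"].to_numpy()
    return RawRecording(
        traces=traces,
        sampling_rate=sidecar["sampling_rate"],
        ground_truth_times=truth_times,
        ground_truth_labels=truth_labels,
        meta=sidecar.get("meta", {}),
    )


# -- KlustaKwik-style text ----------------------------------------------------
def write_fet(path: str, fm: FeatureMatrix, int_scale: float = 1000.0) -> str:
    """Integer-scaled feature file: first line = feature count."""
    vals = np.round(fm.values * int_scale).astype(np.int64)
    with open(path, "w") as fh:
        fh.write(f"{fm.n_features}\n")
        np.savetxt(fh, vals, fmt="%d")
    return path


def write_clu(path: str, labels: np.ndarray, n_clusters: int | None = None) -> str:
    """Cluster file: first line = cluster count, then one label per spike."""
    labels = np.asarray(labels, dtype=int)
    if n_clusters is None:
        n_clusters = len(np.unique(labels))
    with open(path, "w") as fh:
        fh.write(f"{n_clusters}\n")
        np.savetxt(fh, labels, fmt="%d")
    return path


def read_clu(path: str):
    vals = np.loadtxt(path, dtype=int)
    return int(vals[0]), vals[1:]


def write_labels_csv(path: str, labels: np.ndarray) -> str:
    import pandas as pd

    pd.DataFrame(
        {"spike": np.arange(len(labels)), "cluster": np.asarray(labels, dtype=int)}
    ).to_csv(path, index=False)
    return path


def write_features_csv(path: str, fm: FeatureMatrix) -> str:
    import pandas as pd

    pd.DataFrame(fm.values, columns=fm.labels).to_csv(path, index=False)
    return path


# -- models -------------------------------------------------------------------
def write_model_json(path: str, result: SortingResult) -> str:
    payload = {
        "model": result.model.to_dict(),
        "centers": result.centers.centers.tolist(),
        "n_clusters": result.centers.n_found,
        "feature_ids": (
            [f.label for f in result.feature_ids] if result.feature_ids else None
        ),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path


def read_model_json(path: str) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    payload["model"] = MixtureModel.from_dict(payload["model"])
    payload["centers"] = np.asarray(payload["centers"], dtype=float)
    return payload
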