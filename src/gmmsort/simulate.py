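"""Synthetic extracellular recordings with ground truth.

Emulates the structure of the classic simulated benchmark recordings used to
evaluate spike sorters: a bank of average spike waveform shapes, three target
neurons superimposed on ~60 s of background activity made of low-amplitude
spikes from the remaining shapes plus Gaussian noise, at a controllable
signal-to-noise ratio.  The waveform shapes here are parametric (sums of
Gaussian lobes spanning realistic trough widths of 0.1-0.4 ms and total
durations up to ~1.2 ms) rather than a database of recorded averages, so the
whole pipeline can be exercised without any external data.

Everything is a pure function of the spec, including its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import WaveformSet
from .preprocess import RawRecording

__all__ = [
    "SimulationSpec",
    "make_template_bank",
    "synthesize",
    "synthesize_waveforms",
    "subsample_for_symmetry",
]

REFRACTORY_MS = 2.0


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a synthetic recording.

    snr is the ratio of each target neuron's trough amplitude to the SD of
    the background activity; firing rates are per-neuron Poisson rates with a
    2 ms refractory period.
    """

    n_target_neurons: int = 3
    duration: float = 60.0  # seconds
    sampling_rate: float = 24_000.0  # Hz
    template_bank_size: int = 24
    snr: float | tuple = 10.0
    firing_rates: float | tuple = 5.0  # Hz
    background_rate: float = 5000.0  # Hz, low-amplitude background spikes
    outlier_fraction: float = 0.0  # probability of a coincident companion spike
    window: int = 64  # samples per snippet / template
    min_template_distance: float = 2.0  # L2 floor between target templates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template_bank_size < self.n_target_neurons:
            raise ValueError("template bank smaller than target neuron count")
        snr = np.broadcast_to(np.asarray(self.snr, float), (self.n_target_neurons,))
        rates = np.broadcast_to(
            np.asarray(self.firing_rates, float), (self.n_target_neurons,)
        )
        if np.any(snr <= 0) or np.any(rates <= 0) or self.background_rate <= 0:
            raise ValueError("rates and snr must be positive")
        if self.duration * rates.min() < 50:
            warnings.warn(
                "fewer than 50 expected spikes for the sparsest neuron",
                RuntimeWarning,
                stacklevel=2,
            )

    @property
    def snr_per_neuron(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.snr, float), (self.n_target_neurons,)
        ).copy()

    @property
    def rates_per_neuron(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.firing_rates, float), (self.n_target_neurons,)
        ).copy()


def _shape(t_ms: np.ndarray, trough_w, peak_w, peak_amp, peak_delay, pre_amp, pre_w):
    """Triphasic spike shape: small positive pre-hump, negative trough,
    slower positive after-wave."""
    y = (
        pre_amp * np.exp(-0.5 * ((t_ms + 0.35) / pre_w) ** 2)
        - np.exp(-0.5 * (t_ms / trough_w) ** 2)
        + peak_amp * np.exp(-0.5 * ((t_ms - peak_delay) / peak_w) ** 2)
    )
    return y


def make_template_bank(spec: SimulationSpec) -> np.ndarray:
    """Bank of unit-trough spike templates, (bank_size, window).

    Templates are smooth triphasic shapes with varied trough width, after-wave
    amplitude/width and asymmetry; each is normalized to |trough| = 1.  The
    first ``n_target_neurons`` templates are rejection-sampled so their
    pairwise L2 distance is at least ``min_template_distance``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    n = spec.window
    t_ms = (np.arange(n) - n // 2) / spec.sampling_rate * 1e3

    def draw() -> np.ndarray:
        while True:
            y = _shape(
                t_ms,
                trough_w=rng.uniform(0.1, 0.3),
                peak_w=rng.uniform(0.2, 0.6),
                peak_amp=rng.uniform(0.2, 0.75),
                peak_delay=rng.uniform(0.25, 0.8),
                pre_amp=rng.uniform(0.0, 0.25),
                pre_w=rng.uniform(0.08, 0.2),
            )
            # taper the edges so inserted templates do not leave steps
            y = y * np.hanning(n)
            if -y.min() > np.abs(y.max()):  # trough must dominate
                return y / np.abs(y.min())

    # greedy farthest-point selection of the target templates from a candidate
    # pool, so the distinctness floor is met for any seed: the target neurons
    # model *different* cells, not random draws that may nearly coincide
    pool_size = max(50, 4 * spec.template_bank_size)
    for attempt in range(6):
        pool = np.stack([draw() for _ in range(pool_size)])
        idx = [0]
        while len(idx) < spec.n_target_neurons:
            d = np.min(
                np.linalg.norm(pool[:, None, :] - pool[idx][None, :, :], axis=2),
                axis=1,
            )
            best = int(np.argmax(d))
            if d[best] < spec.min_template_distance:
                break
            idx.append(best)
        if len(idx) == spec.n_target_neurons:
            targets = [pool[i] for i in idx]
            rest_pool = [pool[i] for i in range(pool_size) if i not in idx]
            rest = rest_pool[: spec.template_bank_size - spec.n_target_neurons]
            while len(rest) < spec.template_bank_size - spec.n_target_neurons:
                rest.append(draw())
            return np.stack(targets + rest)
        pool_size *= 2
    raise RuntimeError("could not satisfy the template distance floor")


def _poisson_train(rng, rate_hz, duration, fs, refractory_ms=REFRACTORY_MS):
    """Poisson event times (sample indices) with an absolute refractory period."""
    refr = refractory_ms * 1e-3
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_hz) + refr
        if t >= duration:
            break
        times.append(int(round(t * fs)))
    return np.array(times, dtype=int)


def synthesize(spec: SimulationSpec) -> RawRecording:
    """Render a single-channel synthetic recording with ground truth.

    Background = low-amplitude spikes drawn from the non-target templates at
    the background rate, plus white Gaussian noise; target amplitudes are set
    so that trough amplitude / background SD equals the requested snr.  Truth
    times point at each target spike's trough sample.  With
    ``outlier_fraction > 0`` a matching fraction of target spikes get a
    companion spike from another target neuron within 0.5 ms (summed
    waveforms), emulating coincident-spike outliers.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    bank = make_template_bank(spec)
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    w = spec.window
    trough_at_tpl = np.argmin(bank, axis=1)  # per-template trough sample

    trace = np.zeros(n + 2 * w)
    # template-based background
    bg_templates = bank[spec.n_target_neurons :]
    bg_times = _poisson_train(rng, spec.background_rate, spec.duration, fs, 0.0)
    for t in bg_times:
        tpl = bg_templates[rng.integers(len(bg_templates))]
        amp = rng.uniform(0.02, 0.08)
        trace[t : t + w] += amp * tpl
    gauss_sd = 0.5 * trace[w:-w].std() if len(bg_times) else 0.02
    trace += rng.normal(0.0, gauss_sd, size=trace.shape)
    trace -= trace[w:-w].mean()  # background is AC-coupled (no DC offset)
    sigma_bg = trace[w:-w].std()

    snrs = spec.snr_per_neuron
    rates = spec.rates_per_neuron
    truth_times: list[int] = []
    truth_labels: list[int] = []
    for neuron in range(spec.n_target_neurons):
        tpl = bank[neuron]
        amp = snrs[neuron] * sigma_bg
        times = _poisson_train(rng, rates[neuron], spec.duration, fs)
        trough_at = int(trough_at_tpl[neuron])
        for t in times:
            start = t + w - trough_at  # trough lands at sample t
            trace[start : start + w] += amp * tpl
            truth_times.append(t)
            truth_labels.append(neuron + 1)
            if spec.outlier_fraction > 0 and rng.random() < spec.outlier_fraction:
                other = int(rng.integers(spec.n_target_neurons))
                if other == neuron:
                    other = (other + 1) % spec.n_target_neurons
                dt = int(rng.uniform(-0.5e-3, 0.5e-3) * fs)
                t2 = t + dt
                if 0 <= t2 < n:
                    start2 = t2 + w - int(trough_at_tpl[other])
                    trace[start2 : start2 + w] += snrs[other] * sigma_bg * bank[other]
                    truth_times.append(t2)
                    truth_labels.append(other + 1)

    order = np.argsort(truth_times)
    return RawRecording(
        traces=trace[w : w + n][None, :],
        sampling_rate=fs,
        ground_truth_times=np.array(truth_times)[order],
        ground_truth_labels=np.array(truth_labels)[order],
        meta={
            "sigma_background": float(sigma_bg),
            "snr": snrs.tolist(),
            "firing_rates": rates.tolist(),
            "seed": spec.seed,
            "outlier_fraction": spec.outlier_fraction,
        },
    )


def synthesize_waveforms(spec: SimulationSpec) -> WaveformSet:
    """Directly sample labeled spike snippets (no continuous trace).

    Each spike is its neuron's unit-trough template plus white Gaussian noise
    of SD 1/snr per sample — the detection stage is bypassed, so this models
    classification difficulty only.  Spike counts follow the firing rates
    over the spec duration.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    bank = make_template_bank(spec)
    snrs = spec.snr_per_neuron
    rates = spec.rates_per_neuron
    wfs = []
    labels = []
    for neuron in range(spec.n_target_neurons):
        count = max(1, rng.poisson(rates[neuron] * spec.duration))
        noise = rng.normal(0.0, 1.0 / snrs[neuron], size=(count, spec.window))
        wfs.append(bank[neuron][None, :] + noise)
        labels.append(np.full(count, neuron + 1))
    waveforms = np.vstack(wfs)
    labels = np.concatenate(labels)
    perm = rng.permutation(len(labels))
    return WaveformSet(
        waveforms=waveforms[perm],
        sampling_rate=spec.sampling_rate,
        n_channels=1,
        samples_per_channel=spec.window,
        true_labels=labels[perm],
        meta={"seed": spec.seed, "snr": snrs.tolist()},
    )


def subsample_for_symmetry(
    wfs: WaveformSet, target_class: int, index: float, seed: int = 0
) -> WaveformSet:
    """Equalize class counts, then subsample one class to ``index`` percent.

    The symmetry index models firing-rate asymmetry: all classes are first
    subsampled (without replacement) to the minimum class count, then the
    target class is reduced to round(index% of that count), at least 1 spike.
    """
    if not 0 < index <= 100:
        raise ValueError("index must be in (0, 100]")
    if wfs.true_labels is None:
        raise ValueError("true labels required")
    rng = np.random.default_rng(seed)
    classes = np.unique(wfs.true_labels)
    if target_class not in classes:
        raise ValueError(f"class {target_class} not present")
    n_min = min(int(np.sum(wfs.true_labels == c)) for c in classes)
    keep_idx = []
    for c in classes:
        idx = np.flatnonzero(wfs.true_labels == c)
        idx = rng.choice(idx, size=n_min, replace=False)
        if c == target_class:
            n_keep = max(1, int(round(index / 100.0 * n_min)))
            idx = rng.choice(idx, size=n_keep, replace=False)
        keep_idx.append(idx)
    keep = np.sort(np.concatenate(keep_idx))
    if keep.size == 0:
        raise ValueError("subsampling produced an empty set")
    return wfs.subset(keep)
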