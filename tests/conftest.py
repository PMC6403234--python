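import numpy as np
import pytest

from gmmsort import PipelineConfig, SimulationSpec, synthesize_waveforms


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def three_neuron_waveforms():
    """Labeled snippets from three clearly distinct units, moderate size."""
    spec = SimulationSpec(duration=40.0, snr=10.0, seed=3)
    return synthesize_waveforms(spec)


@pytest.fixture(scope="session")
def fast_config():
    """Pipeline config scaled for unit tests (fewer EM restarts)."""
    from gmmsort import FitOptions

    return PipelineConfig(
        fit_options=FitOptions(n_replicates=4, max_iterations=2000),
        scoring_max_iterations=200,
    )


def blobs_5d(seed: int, n_per: int = 300, sep: float = 8.0, k: int = 3):
    """Well-separated spherical clusters in 5-D (unit variance per axis)."""
    rng = np.random.default_rng(seed)
    centers = np.zeros((k, 5))
    for i in range(k):
        centers[i, i % 5] = sep * (i + 1) / k
        centers[i, (i + 2) % 5] = -sep * (i % 2)
    x = np.vstack([rng.normal(c, 1.0, size=(n_per, 5)) for c in centers])
    labels = np.repeat(np.arange(1, k + 1), n_per)
    perm = rng.permutation(len(labels))
    return x[perm], labels[perm], centers
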