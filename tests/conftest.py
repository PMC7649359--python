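import numpy as np
import pytest

from mvfeeg import LatencyModel, SimulationConfig, generate_dataset

#: reduced montage covering C3/C4 and their Laplacian neighborhoods
TEN_CHANNELS = ("C3", "FC1", "FC5", "CP1", "CP5", "C4", "FC2", "FC6", "CP2", "CP6")

CONDS = ("NV", "CV", "IV")


def small_config(**kw) -> SimulationConfig:
    defaults = dict(
        n_subjects=3, n_runs=2, trials_per_run=12, fs=250.0,
        channels=TEN_CHANNELS, n_left_handed=1, seed=42,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_experiment():
    """A 3-subject, 2-run, 12-trials-per-run synthetic experiment."""
    return generate_dataset(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def fixed_latency_config():
    """Single right-handed subject with near-deterministic pedal at 2 s."""
    return small_config(
        n_subjects=1, n_runs=1, trials_per_run=60, n_left_handed=0,
        latency={c: LatencyModel(2.0, 0.001, 0.0) for c in CONDS},
    )
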