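import numpy as np
import pytest

from milkpk import ConcProfile, RunConfig, calibrate_defaults, simulate_crossover


def make_profile(times, concs, subject="s1", matrix="plasma", dose=2.0,
                 lloq=0.04, period=1, blq=None):
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if blq is None:
        blq = np.zeros(times.size, dtype=bool)
    return ConcProfile(subject_id=subject, period=period, dose=dose,
                       matrix=matrix, times=times,
                       concs=np.where(blq, np.nan, concs), blq=np.asarray(blq),
                       lloq=lloq)


@pytest.fixture(scope="session")
def config2():
    return calibrate_defaults(2)


@pytest.fixture(scope="session")
def config4():
    return calibrate_defaults(4)


@pytest.fixture(scope="session")
def crossover_study(config2, config4):
    """One default-calibrated crossover study (8 sheep, CV 0.10, seed 42)."""
    ds, truth = simulate_crossover(config2, config4, seed=42)
    return ds, truth


@pytest.fixture()
def run_config():
    return RunConfig()
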