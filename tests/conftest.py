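import numpy as np
import pytest

from rotsf import RotSFConfig, SimulationSpec, SurvivalDataset, fit, generate_ph_data


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset():
    """10 subjects, 2 covariates, mixed censoring; the first covariate
    separates early from late deaths."""
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
    events = np.array([1, 1, 1, 0, 1, 1, 0, 1, 1, 1])
    x1 = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0, 1.0])
    x2 = np.array([0.3, -1.2, 0.8, 0.1, -0.5, 1.4, -0.9, 0.2, 0.6, -0.1])
    return SurvivalDataset(times, events, np.column_stack([x1, x2]), ("grp", "noise"))


@pytest.fixture(scope="session")
def signal_data():
    """Moderate-size PH data with one strong covariate."""
    spec = SimulationSpec(n=150, p=5, beta=(1.5, 0.0, 0.0, 0.0, 0.0),
                          target_censoring_rate=0.3, seed=11)
    return generate_ph_data(spec)


@pytest.fixture(scope="session")
def signal_model(signal_data):
    return fit(signal_data, RotSFConfig(L=30, M=2, seed=5))


def random_survival_data(rng, n, max_time=10):
    """Small random right-censored dataset with possible ties."""
    times = rng.integers(1, max_time, n).astype(float)
    events = rng.integers(0, 2, n)
    if events.sum() == 0:
        events[rng.integers(0, n)] = 1
    return times, events
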