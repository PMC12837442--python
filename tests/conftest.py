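import warnings

import numpy as np
import pytest

from gaitdp.simulate import GaitScenario, simulate


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free from-standstill walking trial with its ground truth."""
    sc = GaitScenario(seed=11, noise_acc=0.0, noise_gyro=0.0, noise_yaw_deg=0.0)
    rec, truth = simulate(sc)
    return sc, rec, truth


@pytest.fixture(scope="session")
def steady_trial():
    """Noise-free steady-state walking trial (no initiation segment)."""
    sc = GaitScenario(seed=11, noise_acc=0.0, noise_gyro=0.0, noise_yaw_deg=0.0, initiation=False)
    rec, truth = simulate(sc)
    return sc, rec, truth


def true_ic_indices(rec, truth):
    return np.round((truth.ic_times - rec.t[0]) * rec.fs).astype(int)


def true_ms_indices(rec, truth):
    return np.round((truth.ms_times - rec.t[0]) * rec.fs).astype(int)
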