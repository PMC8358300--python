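import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from posturo import (
    COPTrajectory,
    ConditionSway,
    SwayParams,
    center_trajectory,
    default_params,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_trajectory():
    """Random centered trajectory factory (small n for oracle checks)."""

    def _make(n=50, fs=100.0, scale=5.0, seed=0):
        r = np.random.default_rng(seed)
        traj = COPTrajectory(
            ap=r.normal(0, scale, n), ml=r.normal(0, scale, n),
            sampling_rate=fs,
        )
        return center_trajectory(traj)

    return _make


@pytest.fixture
def make_sinusoid():
    """Pure sinusoid trajectory on one axis, integer number of cycles."""

    def _make(amplitude=10.0, freq=1.0, fs=200.0, duration=20.0, axis="ap"):
        n = round(duration * fs)
        t = np.arange(n) / fs
        x = amplitude * np.sin(2 * np.pi * freq * t)
        zeros = np.zeros(n)
        ap, ml = (x, zeros) if axis == "ap" else (zeros, x)
        return COPTrajectory(ap=ap, ml=ml, sampling_rate=fs, centered=False)

    return _make


@pytest.fixture(scope="session")
def calibrated_params():
    return default_params()


@pytest.fixture(scope="session")
def small_params():
    """Two contrasting conditions with short, fast trials."""
    return SwayParams(
        conditions={
            1: ConditionSway(rms_ap_mm=4.0, rms_ml_mm=1.5,
                             cutoff_ap_hz=1.5, cutoff_ml_hz=2.0),
            4: ConditionSway(rms_ap_mm=7.0, rms_ml_mm=4.0,
                             cutoff_ap_hz=1.7, cutoff_ml_hz=1.5),
        },
        sampling_rate=100.0,
        trial_duration=4.0,
    )
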