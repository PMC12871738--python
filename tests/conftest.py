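import numpy as np
import pytest

from mudra import spike_features as sf
from mudra import synthetic_data as sd


def spikes_from_rate(rate_fn, t0: float, t1: float) -> np.ndarray:
    """Deterministic spike times whose ISIs track a rate function (pps)."""
    times = [t0]
    t = t0
    while True:
        dt = 1.0 / rate_fn(t)
        for _ in range(3):  # midpoint refinement
            dt = 1.0 / rate_fn(t + dt / 2)
        t = t + dt
        if t > t1:
            break
        times.append(t)
    return np.array(times)


def make_profile(times, rates) -> sf.SmoothedRate:
    """A SmoothedRate built directly from a constructed profile (no SVR)."""
    return sf.SmoothedRate(
        eval_times=np.asarray(times, float), rate=np.asarray(rates, float)
    )


def recovery_pool(cv: float, seed: int = 0) -> sd.SimGroundTruth:
    """Linear-rate pool for hysteresis recovery: three persistent low-threshold
    reporters and one late test unit with delta = 4 %MVC, gain = 0.5 pps/%MVC,
    so the ground-truth unit-wise ΔF of the test unit is 2.0 pps."""
    return sd.SimGroundTruth(
        thresholds=np.array([2.0, 4.0, 6.0, 14.0]),
        gains=0.5,
        baselines=np.array([11.0, 10.5, 10.0, 9.0]),
        deltas=np.array([10.0, 10.0, 10.0, 4.0]),
        pic_amp=0.0,
        isi_cv=cv,
        seed=seed,
    )


@pytest.fixture(scope="session")
def ramp30():
    return sd.make_torque_ramp(30.0, trial_id="ramp30")


@pytest.fixture(scope="session")
def linear_train():
    """Noiseless spikes from a 5 -> 15 pps linear rate over 10 s."""
    times = spikes_from_rate(lambda t: 5.0 + t, 0.0, 10.0)
    return sf.SpikeTrain(unit_id="lin", spike_times=times)


@pytest.fixture(scope="session")
def cohort_small():
    df, truth = sd.simulate_cohort(n_participants=12, seed=5, n_trials_per_intensity=1)
    return df, truth
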