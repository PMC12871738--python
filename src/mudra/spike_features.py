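"""Per-unit discharge features from decomposed motor unit spike trains.

Decomposed motor unit spike trains are turned into instantaneous discharge
rates (IDR, the reciprocal of each interspike interval), smoothed into a
continuous rate profile by support vector regression, and combined with the
synchronized torque trace to yield basic per-unit features: recruitment and
derecruitment thresholds (%MVC at the first and final spike) and initial,
peak, and final discharge rates read from the smoothed profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt
from sklearn.svm import SVR

logger = logging.getLogger("mudra")

#: minimum spikes required before a unit enters any feature computation
MIN_SPIKES = 4
#: minimum active span (s) for rate smoothing
MIN_SPAN_S = 1.0


class FeatureUndefinedError(ValueError):
    """A feature cannot be computed for this unit (too few spikes, degenerate span...)."""


@dataclass(frozen=True)
class SmoothingConfig:
    """Support-vector-regression smoothing settings.

    The RBF length scale is expressed in seconds and converted to the kernel
    ``gamma = 1 / (2 * length_scale**2)``. Defaults are chosen so that a
    noiseless linearly increasing discharge rate is recovered to well within
    0.5 pps on the interior of the active period.
    """

    kernel: str = "rbf"
    C: float = 10.0
    epsilon: float = 0.01
    length_scale_s: float = 2.5
    #: evaluation-grid rate (Hz); by convention the torque sampling rate
    grid_hz: float = 2048.0
    min_spikes: int = MIN_SPIKES

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.length_scale_s**2)


@dataclass(frozen=True)
class TorqueFilterConfig:
    """Offline low-pass filter applied to the raw torque trace."""

    order: int = 5
    cutoff_hz: float = 10.0


@dataclass
class TrialRecord:
    """One ramp contraction: torque trace (as %MVC) plus task metadata."""

    trial_id: str
    torque: np.ndarray  # %MVC per sample
    sample_rate: float = 2048.0
    target_intensity: float = 30.0  # %MVC
    ramp_up_s: float = 10.0
    ramp_down_s: float = 10.0
    mvc_value: float = 1.0  # device units used to normalize

    def __post_init__(self) -> None:
        self.torque = np.asarray(self.torque, dtype=float)
        lo, hi = self.torque.min(), self.torque.max()
        if lo < -5.0 or hi > 110.0:
            raise ValueError(
                f"trial {self.trial_id}: torque outside plausible %MVC band "
                f"[-5, 110] (range {lo:.1f}..{hi:.1f})"
            )

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.torque.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return (self.torque.size - 1) / self.sample_rate

    def torque_at(self, t: float | np.ndarray) -> np.ndarray:
        """Torque (%MVC) linearly interpolated at exact instants ``t``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.duration + 1e-9):
            raise ValueError(
                f"trial {self.trial_id}: instant outside torque record "
                f"[0, {self.duration:.3f}] s"
            )
        return np.interp(t, self.time, self.torque)


@dataclass
class SpikeTrain:
    """Ordered spike instants (s) of one motor unit within one trial."""

    unit_id: str
    spike_times: np.ndarray
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size >= 2 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError(f"unit {self.unit_id}: spike times not strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def first_spike(self) -> float:
        return float(self.spike_times[0])

    @property
    def last_spike(self) -> float:
        return float(self.spike_times[-1])

    @property
    def span(self) -> float:
        return self.last_spike - self.first_spike

    def validate_against(self, trial: TrialRecord) -> None:
        if self.first_spike < -1e-9 or self.last_spike > trial.duration + 1e-9:
            raise ValueError(
                f"unit {self.unit_id}: spikes outside torque record of trial {trial.trial_id}"
            )


@dataclass
class SmoothedRate:
    """Continuous discharge-rate estimate over a unit's active period."""

    eval_times: np.ndarray  # s, torque-grid spacing, spans [first, last spike]
    rate: np.ndarray  # pps, strictly positive
    fit_diagnostics: dict = field(default_factory=dict)

    @property
    def t_start(self) -> float:
        return float(self.eval_times[0])

    @property
    def t_end(self) -> float:
        return float(self.eval_times[-1])

    def rate_at(self, t: float | np.ndarray) -> np.ndarray:
        """Smoothed rate linearly interpolated on the evaluation grid."""
        return np.interp(np.asarray(t, dtype=float), self.eval_times, self.rate)

    def covers(self, t: float) -> bool:
        return self.t_start - 1e-9 <= t <= self.t_end + 1e-9


@dataclass
class UnitMetrics:
    """Per-unit derived features, filled progressively by the pipeline."""

    unit_id: str
    trial_id: str
    recruitment_threshold: float  # %MVC at first spike
    derecruitment_threshold: float  # %MVC at final spike
    initial_rate: float  # pps, smoothed rate at first spike
    peak_rate: float  # pps, max of the smoothed profile
    final_rate: float  # pps, smoothed rate at final spike
    peak_time: float  # s, instant of the smoothed-profile maximum
    delta_f: float = np.nan
    n_reporters: int = 0
    brace_height: float = np.nan  # %rTri, signed
    deviation_location: float = np.nan  # normalized abscissa in [0, 1]
    accel_slope: float = np.nan  # pps per %MVC
    atten_slope: float = np.nan  # pps per %MVC


def compute_idr(train: SpikeTrain) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous discharge rate: one 1/ISI value per interspike interval.

    Each rate value is timestamped at the later spike of its interval.

    Returns
    -------
    times, rates : arrays of length n_spikes - 1, rates in pps.
    """
    if train.n_spikes < 2:
        raise FeatureUndefinedError(
            f"unit {train.unit_id}: IDR needs >=2 spikes, got {train.n_spikes}"
        )
    isi = np.diff(train.spike_times)
    return train.spike_times[1:], 1.0 / isi


def filter_torque(
    raw: np.ndarray, sample_rate: float, config: TorqueFilterConfig | None = None
) -> np.ndarray:
    """Zero-phase low-pass Butterworth smoothing of a raw torque trace."""
    config = config or TorqueFilterConfig()
    b, a = butter(config.order, config.cutoff_hz, fs=sample_rate)
    return filtfilt(b, a, np.asarray(raw, dtype=float))


def smooth_discharge(train: SpikeTrain, config: SmoothingConfig | None = None) -> SmoothedRate:
    """Smooth a spike train's IDR into a continuous rate profile by SVR.

    The regression inputs are the IDR timestamps, the targets the IDR values;
    the fitted function is evaluated on a grid at the torque sample spacing
    clipped to [first spike, last spike]. The fit is deterministic given the
    input and config.
    """
    config = config or SmoothingConfig()
    if train.n_spikes < config.min_spikes:
        raise FeatureUndefinedError(
            f"unit {train.unit_id}: smoothing needs >={config.min_spikes} spikes, "
            f"got {train.n_spikes}"
        )
    if train.span < MIN_SPAN_S:
        raise FeatureUndefinedError(
            f"unit {train.unit_id}: active span {train.span:.3f} s < {MIN_SPAN_S} s"
        )
    t, r = compute_idr(train)
    # center times so the kernel sees the same geometry wherever the burst sits
    t0 = train.first_spike
    svr = SVR(kernel=config.kernel, C=config.C, epsilon=config.epsilon, gamma=config.gamma)
    svr.fit((t - t0)[:, None], r)
    n_grid = int(np.floor(train.span * config.grid_hz)) + 1
    grid = train.first_spike + np.arange(n_grid) / config.grid_hz
    if grid[-1] < train.last_spike - 1e-12:
        grid = np.append(grid, train.last_spike)
    rate = svr.predict((grid - t0)[:, None])
    resid = r - svr.predict((t - t0)[:, None])
    diagnostics = {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "max_abs_resid": float(np.max(np.abs(resid))),
        "n_support": int(svr.support_.size),
    }
    # the rate of a discharging unit is positive by definition; guard the
    # rare SVR undershoot at the edges
    rate = np.maximum(rate, 1e-6)
    return SmoothedRate(eval_times=grid, rate=rate, fit_diagnostics=diagnostics)


def unit_features(
    train: SpikeTrain, smoothed: SmoothedRate, trial: TrialRecord
) -> UnitMetrics:
    """Thresholds and initial/peak/final discharge rates for one unit.

    Recruitment and derecruitment thresholds are the torque (%MVC) linearly
    interpolated at the exact first and final spike instants; initial and
    final rates are the smoothed rate at those instants; peak rate is the
    maximum of the smoothed profile.
    """
    train.validate_against(trial)
    i_peak = int(np.argmax(smoothed.rate))
    return UnitMetrics(
        unit_id=train.unit_id,
        trial_id=trial.trial_id,
        recruitment_threshold=float(trial.torque_at(train.first_spike)),
        derecruitment_threshold=float(trial.torque_at(train.last_spike)),
        initial_rate=float(smoothed.rate_at(train.first_spike)),
        peak_rate=float(smoothed.rate[i_peak]),
        final_rate=float(smoothed.rate_at(train.last_spike)),
        peak_time=float(smoothed.eval_times[i_peak]),
    )
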