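"""Estimates of persistent-inward-current (PIC) contributions to discharge.

Two complementary estimates are computed from smoothed discharge-rate
profiles:

* **Discharge-rate hysteresis (ΔF)** — the paired motor unit analysis. For a
  later-recruited *test* unit and an earlier-recruited *reporter* unit whose
  rate proxies the shared synaptic drive, ΔF is the reporter's smoothed rate
  at the test unit's recruitment minus at its derecruitment. Pairs enter the
  analysis only when three criteria hold: the test unit is recruited at least
  1 s after the reporter (full PIC activation), the rate-rate correlation is
  r >= 0.7 (common synaptic input), and the reporter modulates its rate by at
  least 0.5 pps while the test unit is active. A unit-wise ΔF averages the
  pair values over all eligible reporters.

* **Ascending nonlinearity (brace height)** — the maximal orthogonal
  deviation of the ascending smoothed-rate profile from the straight chord
  joining recruitment to peak discharge, normalized to the altitude of the
  right triangle erected on that chord (%rTri). Deviations above the chord
  (concave-down, saturating, PIC-like) are positive. The acceleration and
  attenuation slopes of rate versus torque are fitted on the two segments of
  the ascending limb split at the brace-height deviation location.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spike_features import (
    SmoothedRate,
    SmoothingConfig,
    SpikeTrain,
    TrialRecord,
    FeatureUndefinedError,
    MIN_SPAN_S,
    smooth_discharge,
    unit_features,
)

logger = logging.getLogger("mudra")


@dataclass(frozen=True)
class EligibilityConfig:
    """Pair-eligibility thresholds for the ΔF analysis (field defaults)."""

    min_recruit_delay_s: float = 1.0
    min_rate_correlation: float = 0.7
    min_reporter_range_pps: float = 0.5


@dataclass(frozen=True)
class SlopeConfig:
    """Acceleration/attenuation slope fitting options."""

    #: below this |brace height| the ascending limb is treated as linear and a
    #: single line is reported as both slopes
    min_brace_for_split: float = 2.0
    min_points_per_segment: int = 3


@dataclass
class PairEligibility:
    test_id: str
    reporter_id: str
    recruit_delay: float  # s
    rate_rate_r: float  # Pearson r of smoothed rates over the common period
    reporter_range: float  # pps while test unit active
    eligible: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class DeltaFResult:
    test_id: str
    pair_values: list[float]
    n_reporters: int

    @property
    def unit_wise_delta_f(self) -> float:
        """Mean ΔF over eligible reporters; NaN when none are eligible."""
        if self.n_reporters < 1:
            return float("nan")
        return float(np.mean(self.pair_values))


@dataclass
class BraceHeightResult:
    brace_height: float  # %rTri, signed
    deviation_location: float  # normalized abscissa in [0, 1]
    accel_slope: float = np.nan  # pps per %MVC
    atten_slope: float = np.nan  # pps per %MVC


@dataclass
class UnitProfile:
    """A spike train together with its smoothed rate, as used by pairing."""

    train: SpikeTrain
    smoothed: SmoothedRate


def check_pair_eligibility(
    test: UnitProfile, reporter: UnitProfile, config: EligibilityConfig | None = None
) -> PairEligibility:
    """Evaluate the three ΔF pair criteria for a test/reporter pair.

    The rate-rate correlation is the Pearson r of the two smoothed rates
    sampled on a common grid over the period where both units are active; the
    reporter range is max - min of the reporter's smoothed rate while the
    test unit is active.
    """
    config = config or EligibilityConfig()
    delay = test.train.first_spike - reporter.train.first_spike
    t_lo = max(test.smoothed.t_start, reporter.smoothed.t_start)
    t_hi = min(test.smoothed.t_end, reporter.smoothed.t_end)
    reasons: list[str] = []
    if t_hi <= t_lo:
        return PairEligibility(
            test_id=test.train.unit_id,
            reporter_id=reporter.train.unit_id,
            recruit_delay=delay,
            rate_rate_r=float("nan"),
            reporter_range=float("nan"),
            eligible=False,
            reasons=["no common activity"],
        )
    # common grid at the test unit's evaluation spacing
    mask = (test.smoothed.eval_times >= t_lo - 1e-12) & (
        test.smoothed.eval_times <= t_hi + 1e-12
    )
    grid = test.smoothed.eval_times[mask]
    if grid.size < 3:
        grid = np.linspace(t_lo, t_hi, 3)
    r_test = test.smoothed.rate_at(grid)
    r_rep = reporter.smoothed.rate_at(grid)
    if np.std(r_test) < 1e-12 or np.std(r_rep) < 1e-12:
        rate_r = 0.0
    else:
        rate_r = float(stats.pearsonr(r_test, r_rep).statistic)
    rep_active = reporter.smoothed.rate_at(grid)
    reporter_range = float(rep_active.max() - rep_active.min())

    if delay < config.min_recruit_delay_s:
        reasons.append(
            f"recruit delay {delay:.2f} s < {config.min_recruit_delay_s} s"
        )
    if rate_r < config.min_rate_correlation:
        reasons.append(
            f"rate-rate r {rate_r:.2f} < {config.min_rate_correlation}"
        )
    if reporter_range < config.min_reporter_range_pps:
        reasons.append(
            f"reporter range {reporter_range:.2f} pps < {config.min_reporter_range_pps} pps"
        )
    return PairEligibility(
        test_id=test.train.unit_id,
        reporter_id=reporter.train.unit_id,
        recruit_delay=delay,
        rate_rate_r=rate_r,
        reporter_range=reporter_range,
        eligible=not reasons,
        reasons=reasons,
    )


def delta_f_pair(test: UnitProfile, reporter: UnitProfile) -> float:
    """ΔF for one eligible pair (pps).

    Reporter smoothed rate at the test unit's recruitment instant minus at
    its derecruitment instant (the test unit's first and final spikes). The
    sign is preserved: a reporter discharging faster at test derecruitment
    than at recruitment yields a negative ΔF.
    """
    t_rec = test.train.first_spike
    t_derec = test.train.last_spike
    if not (reporter.smoothed.covers(t_rec) and reporter.smoothed.covers(t_derec)):
        raise FeatureUndefinedError(
            f"pair ({test.train.unit_id}, {reporter.train.unit_id}): test "
            "recruitment/derecruitment outside reporter active span"
        )
    return float(reporter.smoothed.rate_at(t_rec) - reporter.smoothed.rate_at(t_derec))


def unit_wise_delta_f(
    test: UnitProfile,
    reporters: list[UnitProfile],
    config: EligibilityConfig | None = None,
) -> tuple[DeltaFResult, list[PairEligibility]]:
    """Unit-wise ΔF for one test unit: the mean over all eligible reporters.

    Returns the result together with the per-pair eligibility audit. With
    zero eligible reporters the unit-wise value is NaN and the unit is
    excluded from downstream ΔF models (counted in yield diagnostics).
    """
    config = config or EligibilityConfig()
    audits: list[PairEligibility] = []
    values: list[float] = []
    for rep in reporters:
        if rep.train.unit_id == test.train.unit_id:
            continue
        audit = check_pair_eligibility(test, rep, config)
        if audit.eligible:
            try:
                values.append(delta_f_pair(test, rep))
            except FeatureUndefinedError as err:
                logger.warning("%s", err)
                audit.eligible = False
                audit.reasons.append("test instants outside reporter span")
        audits.append(audit)
    return DeltaFResult(test.train.unit_id, values, len(values)), audits


def brace_height(
    smoothed: SmoothedRate, recruit_instant: float, peak_instant: float
) -> BraceHeightResult:
    """Brace height of the ascending smoothed-rate profile (%rTri).

    Both axes are normalized to [0, 1] over [recruitment, peak]. The brace
    height is the signed orthogonal deviation from the recruitment-to-peak
    chord at the point of maximal absolute deviation, divided by the altitude
    of the right triangle on that chord (1/sqrt(2) in normalized units) and
    expressed in percent. On the unit square the ratio reduces to
    ``100 * (y - x)`` at the extreme point, positive above the chord.
    """
    if peak_instant <= recruit_instant:
        raise FeatureUndefinedError("peak must occur after recruitment")
    mask = (smoothed.eval_times >= recruit_instant - 1e-12) & (
        smoothed.eval_times <= peak_instant + 1e-12
    )
    t = smoothed.eval_times[mask]
    r = smoothed.rate[mask]
    if t.size < 3:
        raise FeatureUndefinedError("ascending segment has fewer than 3 evaluation points")
    r0, rp = r[0], r[-1]
    if abs(rp - r0) < 1e-12:
        raise FeatureUndefinedError("zero rate range over the ascending segment")
    x = (t - t[0]) / (t[-1] - t[0])
    y = (r - r0) / (rp - r0)
    dev = y - x  # signed orthogonal distance * sqrt(2)
    i = int(np.argmax(np.abs(dev)))
    return BraceHeightResult(
        brace_height=float(100.0 * dev[i]),
        deviation_location=float(x[i]),
    )


def accel_atten_slopes(
    smoothed: SmoothedRate,
    trial: TrialRecord,
    recruit_instant: float,
    peak_instant: float,
    brace: BraceHeightResult | None = None,
    config: SlopeConfig | None = None,
) -> tuple[float, float]:
    """Acceleration and attenuation slopes of rate vs torque (pps per %MVC).

    The ascending limb (recruitment to the instant of peak smoothed rate) is
    expressed in rate-versus-torque coordinates and split at the abscissa of
    maximal orthogonal deviation from the chord; an ordinary least squares
    line is fitted to each segment. When the profile is essentially linear
    (|brace height| below ``min_brace_for_split``), one line is fitted and
    reported as both slopes.
    """
    config = config or SlopeConfig()
    if brace is None:
        brace = brace_height(smoothed, recruit_instant, peak_instant)
    mask = (smoothed.eval_times >= recruit_instant - 1e-12) & (
        smoothed.eval_times <= peak_instant + 1e-12
    )
    t = smoothed.eval_times[mask]
    r = smoothed.rate[mask]
    tq = trial.torque_at(t)
    if np.isnan(brace.brace_height) or abs(brace.brace_height) < config.min_brace_for_split:
        slope = _ols_slope(tq, r)
        return slope, slope
    t_split = t[0] + brace.deviation_location * (t[-1] - t[0])
    seg1 = t <= t_split + 1e-12
    seg2 = t >= t_split - 1e-12
    accel = (
        _ols_slope(tq[seg1], r[seg1])
        if seg1.sum() >= config.min_points_per_segment
        else float("nan")
    )
    atten = (
        _ols_slope(tq[seg2], r[seg2])
        if seg2.sum() >= config.min_points_per_segment
        else float("nan")
    )
    return accel, atten


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.ptp(x) < 1e-12:
        return float("nan")
    return float(np.polyfit(x, y, 1)[0])


def analyze_trial(
    trial: TrialRecord,
    trains: list[SpikeTrain],
    smoothing: SmoothingConfig | None = None,
    eligibility: EligibilityConfig | None = None,
    slopes: SlopeConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full per-trial feature extraction: thresholds, rates, ΔF, brace height, slopes.

    Returns the per-unit metrics table, the per-pair eligibility audit, and a
    bookkeeping dict of unit counts per drop reason.
    """
    smoothing = smoothing or SmoothingConfig(grid_hz=trial.sample_rate)
    eligibility = eligibility or EligibilityConfig()
    slopes = slopes or SlopeConfig()

    counts = {"units_in": len(trains), "too_few_spikes": 0, "short_span": 0, "analyzed": 0}
    profiles: list[UnitProfile] = []
    for train in trains:
        if train.n_spikes < smoothing.min_spikes:
            counts["too_few_spikes"] += 1
            logger.info(
                "trial %s unit %s dropped: %d spikes < %d",
                trial.trial_id, train.unit_id, train.n_spikes, smoothing.min_spikes,
            )
            continue
        if train.span < MIN_SPAN_S:
            counts["short_span"] += 1
            logger.info(
                "trial %s unit %s dropped: span %.2f s < %.1f s",
                trial.trial_id, train.unit_id, train.span, MIN_SPAN_S,
            )
            continue
        profiles.append(UnitProfile(train, smooth_discharge(train, smoothing)))
    counts["analyzed"] = len(profiles)

    rows, audit_rows = [], []
    for prof in profiles:
        m = unit_features(prof.train, prof.smoothed, trial)
        try:
            br = brace_height(prof.smoothed, prof.train.first_spike, m.peak_time)
            m.brace_height = br.brace_height
            m.deviation_location = br.deviation_location
            m.accel_slope, m.atten_slope = accel_atten_slopes(
                prof.smoothed, trial, prof.train.first_spike, m.peak_time, br, slopes
            )
        except FeatureUndefinedError as err:
            logger.info("trial %s: %s", trial.trial_id, err)
        dfres, audits = unit_wise_delta_f(prof, profiles, eligibility)
        m.delta_f = dfres.unit_wise_delta_f
        m.n_reporters = dfres.n_reporters
        rows.append(vars(m))
        for a in audits:
            audit_rows.append(
                {
                    "trial_id": trial.trial_id,
                    "test_id": a.test_id,
                    "reporter_id": a.reporter_id,
                    "recruit_delay_s": a.recruit_delay,
                    "rate_rate_r": a.rate_rate_r,
                    "reporter_range_pps": a.reporter_range,
                    "eligible": a.eligible,
                    "reasons": "; ".join(a.reasons),
                }
            )
    metrics = pd.DataFrame(rows)
    audit = pd.DataFrame(
        audit_rows,
        columns=[
            "trial_id", "test_id", "reporter_id", "recruit_delay_s",
            "rate_rate_r", "reporter_range_pps", "eligible", "reasons",
        ],
    )
    return metrics, audit, counts
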