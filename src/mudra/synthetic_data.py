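"""Synthetic motor-unit pools, ramp trials, and hormone cohorts.

The generator carries its injected ground truth so the analysis pipeline can
be tested for parameter recovery end to end. Two levels are provided:

* **Pool / trial level** — a triangular torque ramp (10 s up, 10 s down, to
  30/50/70 %MVC by default) drives a recruitment-ordered pool. Unit *i*
  discharges while torque exceeds its recruitment threshold on the ascent
  and until torque falls below threshold minus a hysteresis offset delta on
  the descent (the PIC-like prolongation that the paired-unit ΔF analysis
  estimates: for a linear rate profile, ΔF = gain x delta). The instantaneous
  rate is baseline + gain x (torque - threshold) plus a saturating
  acceleration term that produces the concave-down onset measured by brace
  height. Interspike intervals follow a gamma renewal process with a given
  coefficient of variation (CV = 0 is deterministic). Baselines decrease with
  threshold so earlier-recruited units keep higher rates (onion-skin rate
  coding).

* **Cohort level** — a 40-participant x 3-phase x 3-intensity design with
  EF/LF/ML-shaped estradiol and progesterone panels (E2 peaks in the late
  follicular phase, P4 in the mid luteal), lognormal between-participant
  variation, a configurable proportion of anovulatory/atypical participants,
  variable motor-unit yield per trial, and outcome tables perturbed by
  injected phase, session and hormone effects on top of participant and
  trial random intercepts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_rules import SessionContext
from .spike_features import SpikeTrain, TrialRecord

PHASES = ("EF", "LF", "ML")
INTENSITIES = (30, 50, 70)


# ---------------------------------------------------------------------------
# torque ramps
# ---------------------------------------------------------------------------


def make_torque_ramp(
    target: float,
    up_s: float = 10.0,
    down_s: float = 10.0,
    rate_hz: float = 2048.0,
    trial_id: str = "trial",
    target_is_intensity: bool = True,
) -> TrialRecord:
    """Triangular torque trace 0 -> target -> 0 (%MVC) at ``rate_hz``."""
    if not 0 < target <= 100:
        raise ValueError(f"target intensity must be in (0, 100], got {target}")
    if up_s <= 0 or down_s <= 0:
        raise ValueError("ramp durations must be positive")
    n = int(round((up_s + down_s) * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    torque = np.where(
        t <= up_s, target * t / up_s, target * np.maximum(0.0, 1 - (t - up_s) / down_s)
    )
    return TrialRecord(
        trial_id=trial_id,
        torque=torque,
        sample_rate=rate_hz,
        target_intensity=target if target_is_intensity else 0.0,
        ramp_up_s=up_s,
        ramp_down_s=down_s,
    )


# ---------------------------------------------------------------------------
# motoneuron pool
# ---------------------------------------------------------------------------


@dataclass
class SimGroundTruth:
    """Injected pool parameters against which recovery is tested.

    thresholds sorted ascending define the recruitment order; ``deltas`` are
    the derecruitment hysteresis offsets (%MVC, >= 0) whose gain-scaled value
    is the ground-truth ΔF; ``pic_amp``/``pic_scale`` shape the saturating
    onset acceleration that sets brace height.
    """

    thresholds: np.ndarray  # %MVC, ascending
    gains: np.ndarray  # pps per %MVC
    baselines: np.ndarray  # pps at recruitment
    deltas: np.ndarray  # hysteresis offsets, %MVC
    pic_amp: float = 3.0  # pps
    pic_scale: float = 3.0  # %MVC e-folding of the onset acceleration
    isi_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, float)
        self.gains = np.broadcast_to(np.asarray(self.gains, float), self.thresholds.shape).copy()
        self.baselines = np.broadcast_to(
            np.asarray(self.baselines, float), self.thresholds.shape
        ).copy()
        self.deltas = np.broadcast_to(np.asarray(self.deltas, float), self.thresholds.shape).copy()
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be sorted ascending (recruitment order)")
        if np.any(self.deltas < 0):
            raise ValueError("hysteresis offsets must be >= 0")

    @property
    def n_units(self) -> int:
        return int(self.thresholds.size)

    def expected_delta_f(self, i: int) -> float:
        """Ground-truth ΔF of unit i against a linear-profile reporter."""
        return float(self.gains[i] * self.deltas[i])


def default_pool(
    n_units: int = 8,
    threshold_range: tuple[float, float] = (2.0, 18.0),
    gain: float = 0.25,
    baseline_at_zero: float = 10.0,
    baseline_slope: float = -0.12,  # pps per %MVC of threshold (onion skin)
    delta: float = 4.0,
    pic_amp: float = 12.0,
    pic_scale: float = 2.5,
    isi_cv: float = 0.15,
    seed: int = 0,
) -> SimGroundTruth:
    """A recruitment-ordered pool with onion-skin baselines and uniform hysteresis.

    The acceleration amplitude/scale defaults put the brace height of a
    mid-pool unit on a 30 %MVC ramp near 40 %rTri; set ``pic_amp=0`` for
    strictly linear rate profiles (where ΔF recovers gain x delta exactly).
    """
    thresholds = np.linspace(*threshold_range, n_units)
    return SimGroundTruth(
        thresholds=thresholds,
        gains=np.full(n_units, gain),
        baselines=baseline_at_zero + baseline_slope * thresholds,
        deltas=np.full(n_units, delta),
        pic_amp=pic_amp,
        pic_scale=pic_scale,
        isi_cv=isi_cv,
        seed=seed,
    )


def _unit_rate(truth: SimGroundTruth, i: int, torque: np.ndarray) -> np.ndarray:
    d = np.maximum(np.asarray(torque, float) - truth.thresholds[i], 0.0)
    return (
        truth.baselines[i]
        + truth.gains[i] * d
        + truth.pic_amp * (1.0 - np.exp(-d / truth.pic_scale))
    )


def simulate_pool_trial(
    truth: SimGroundTruth, trial: TrialRecord, seed: int | None = None
) -> list[SpikeTrain]:
    """Spike trains of the pool discharging through one ramp trial.

    Unit i is recruited at the ascending crossing of its threshold and
    derecruited at the descending crossing of threshold - delta. The first
    spike sits exactly on the recruitment crossing and the last on the
    derecruitment crossing (the final interval is merged with its neighbour
    when shorter than half the local ISI, so the IDR stays well behaved);
    interior intervals are 1/rate scaled by gamma noise with the configured
    CV. Reproducible for a given seed.
    """
    if truth.n_units == 0:
        raise ValueError("empty pool")
    seed = truth.seed if seed is None else seed
    children = np.random.SeedSequence(seed).spawn(truth.n_units)
    t_axis, torque = trial.time, trial.torque
    i_peak = int(np.argmax(torque))
    trains: list[SpikeTrain] = []
    for i in range(truth.n_units):
        theta, delta = truth.thresholds[i], truth.deltas[i]
        asc = torque[: i_peak + 1]
        if theta > asc.max():
            continue  # never recruited
        j_on = int(np.searchsorted(asc, theta))
        # linear interpolation of the exact ascending crossing
        if j_on == 0:
            t_on = t_axis[0]
        else:
            f = (theta - asc[j_on - 1]) / (asc[j_on] - asc[j_on - 1])
            t_on = t_axis[j_on - 1] + f * (t_axis[j_on] - t_axis[j_on - 1])
        desc = torque[i_peak:]
        off_level = theta - delta
        below = np.nonzero(desc < off_level)[0]
        if below.size == 0:
            t_off = t_axis[-1]
        else:
            k = below[0] + i_peak
            f = (torque[k - 1] - off_level) / (torque[k - 1] - torque[k])
            t_off = t_axis[k - 1] + f * (t_axis[k] - t_axis[k - 1])
        rng = np.random.default_rng(children[i])
        cv = truth.isi_cv
        shape = None if cv <= 0 else 1.0 / cv**2
        spikes = [t_on]
        t = t_on
        while True:
            isi = 1.0 / _unit_rate(truth, i, np.interp(t, t_axis, torque))
            # midpoint refinement so the ISI tracks the changing rate
            isi = 1.0 / _unit_rate(truth, i, np.interp(t + isi / 2, t_axis, torque))
            if shape is not None:
                isi = isi * rng.gamma(shape, 1.0 / shape)
            t = t + isi
            if t >= t_off:
                break
            spikes.append(t)
        # snap the last event to the derecruitment crossing
        if len(spikes) > 1 and t_off - spikes[-1] < 0.5 * isi:
            spikes[-1] = t_off
        elif t_off > spikes[-1] + 1e-6:
            spikes.append(t_off)
        if len(spikes) >= 2:
            trains.append(
                SpikeTrain(
                    unit_id=f"u{i:02d}", spike_times=np.array(spikes), trial_id=trial.trial_id
                )
            )
    return trains


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


@dataclass
class CohortEffects:
    """Injected effects on the outcome table.

    ``phase`` maps outcome -> {"LF": shift, "ML": shift} (additive, EF is the
    reference); ``hormones`` maps outcome -> coefficients on the log-hormone
    within/between components (keys ``e2_within``, ``e2_between``,
    ``p4_within``, ``p4_between``).
    """

    phase: dict = field(default_factory=dict)
    hormones: dict = field(default_factory=dict)

    def validate(self, outcomes) -> None:
        for name, spec in list(self.phase.items()) + list(self.hormones.items()):
            if name not in outcomes:
                raise ValueError(f"effect on unknown outcome {name!r}")
            if not isinstance(spec, dict):
                raise ValueError(f"effect spec for {name!r} must be a mapping")


#: per-intensity outcome means and (participant, trial, unit) SDs under the
#: study's task; slope outcomes are generated on the natural-log scale
OUTCOME_MODELS = {
    "peak_rate": {"means": {30: 17.0, 50: 20.0, 70: 25.0}, "sd": (1.5, 0.8, 2.5), "log": False},
    "delta_f": {"means": {30: 5.2, 50: 6.0, 70: 6.8}, "sd": (1.0, 0.5, 1.5), "log": False},
    "brace_height": {"means": {30: 41.0, 50: 42.0, 70: 39.0}, "sd": (5.0, 3.0, 10.0), "log": False},
    "accel_slope": {
        "means": {30: np.log(2.2), 50: np.log(1.3), 70: np.log(0.85)},
        "sd": (0.2, 0.1, 0.4),
        "log": True,
    },
    "atten_slope": {
        "means": {30: np.log(0.33), 50: np.log(0.18), 70: np.log(0.15)},
        "sd": (0.2, 0.1, 0.4),
        "log": True,
    },
}

#: lognormal medians (nmol/L) of the hormone panel by phase
HORMONE_MEDIANS = {
    "e2": {"EF": 0.15, "LF": 0.90, "ML": 0.45},
    "p4": {"EF": 1.5, "LF": 2.0, "ML": 30.0},
}
HORMONE_SIGMA = {"e2": 0.35, "p4": 0.30}
#: anovulatory participants: no LH surge, mid-luteal P4 stays follicular-like
P4_ANOVULATORY_MEDIAN = 4.0

#: mild learning effect across sessions on peak discharge rate (pps)
SESSION_EFFECTS = {"peak_rate": {1: 0.0, 2: 0.2, 3: 0.3}}
#: recruitment-threshold association with each outcome (per %MVC)
RT_COEF = {"peak_rate": -0.05, "delta_f": -0.02, "brace_height": 0.0,
           "accel_slope": 0.0, "atten_slope": 0.0}


def simulate_cohort(
    n_participants: int = 40,
    effects: CohortEffects | None = None,
    seed: int = 0,
    n_trials_per_intensity: int = 2,
    anovulatory_prop: float = 0.2,
    yield_range: tuple[int, int] = (5, 25),
    outcomes: tuple[str, ...] = ("peak_rate", "delta_f", "brace_height",
                                 "accel_slope", "atten_slope"),
) -> tuple[pd.DataFrame, dict]:
    """Full analysis dataset for the three-phase, three-intensity design.

    Returns a tidy unit-level table (one row per decomposed motor unit per
    trial, with hormone panel, session metadata, trial yield as the model
    weight, and all outcome columns) together with the injected ground truth.
    """
    if n_participants < 2:
        raise ValueError("need >=2 participants")
    effects = effects or CohortEffects()
    effects.validate(OUTCOME_MODELS.keys())
    rng = np.random.default_rng(seed)
    rows = []
    hormone_truth = []
    for ip in range(n_participants):
        pid = f"P{ip:03d}"
        anovulatory = bool(rng.random() < anovulatory_prop)
        phase_order = list(rng.permutation(PHASES))
        # hormone panel
        logh = {}
        for h in ("e2", "p4"):
            shift = rng.normal(0.0, 0.2)  # stable individual level
            logh[h] = {}
            for ph in PHASES:
                med = HORMONE_MEDIANS[h][ph]
                if h == "p4" and ph == "ML" and anovulatory:
                    med = P4_ANOVULATORY_MEDIAN
                logh[h][ph] = np.log(med) + shift + rng.normal(0.0, HORMONE_SIGMA[h])
        h_mean = {h: np.mean(list(logh[h].values())) for h in ("e2", "p4")}
        lh_surge_day = None if anovulatory else int(13 + rng.integers(-2, 3))
        u_p = {o: rng.normal(0.0, OUTCOME_MODELS[o]["sd"][0]) for o in outcomes}
        for sess, ph in enumerate(phase_order, start=1):
            if ph == "EF":
                cycle_day = int(rng.integers(2, 5))
            elif ph == "LF":
                cycle_day = (lh_surge_day or 13) - int(rng.integers(1, 3))
            else:
                cycle_day = (lh_surge_day or 13) + int(rng.integers(7, 10))
            for intensity in INTENSITIES:
                for k in range(n_trials_per_intensity):
                    trial_id = f"{pid}_s{sess}_{intensity}_{k}"
                    n_units = int(rng.integers(yield_range[0], yield_range[1] + 1))
                    v_t = {o: rng.normal(0.0, OUTCOME_MODELS[o]["sd"][1]) for o in outcomes}
                    rt = rng.uniform(1.0, 0.7 * intensity, size=n_units)
                    for iu in range(n_units):
                        row = {
                            "participant_id": pid,
                            "session": sess,
                            "phase": ph,
                            "intensity": intensity,
                            "trial_id": trial_id,
                            "unit_id": f"u{iu:02d}",
                            "yield": n_units,
                            "recruitment_threshold": rt[iu],
                            "e2": float(np.exp(logh["e2"][ph])),
                            "p4": float(np.exp(logh["p4"][ph])),
                            "cycle_day": cycle_day,
                            "lh_surge_day": lh_surge_day,
                            "anovulatory": anovulatory,
                        }
                        for o in outcomes:
                            m = OUTCOME_MODELS[o]
                            y = m["means"][intensity]
                            y += SESSION_EFFECTS.get(o, {}).get(sess, 0.0)
                            y += RT_COEF.get(o, 0.0) * rt[iu]
                            y += effects.phase.get(o, {}).get(ph, 0.0)
                            hcoef = effects.hormones.get(o, {})
                            for h in ("e2", "p4"):
                                within = logh[h][ph] - h_mean[h]
                                between = h_mean[h] - np.log(
                                    np.prod(list(HORMONE_MEDIANS[h].values())) ** (1 / 3)
                                )
                                y += hcoef.get(f"{h}_within", 0.0) * within
                                y += hcoef.get(f"{h}_between", 0.0) * between
                            y += u_p[o] + v_t[o] + rng.normal(0.0, m["sd"][2])
                            row[o] = float(np.exp(y)) if m["log"] else float(y)
                        rows.append(row)
        hormone_truth.append({"participant_id": pid, "anovulatory": anovulatory, **h_mean})
    df = pd.DataFrame(rows)
    truth = {
        "seed": seed,
        "n_participants": n_participants,
        "anovulatory_prop": anovulatory_prop,
        "effects": {"phase": effects.phase, "hormones": effects.hormones},
        "session_effects": SESSION_EFFECTS,
        "rt_coef": RT_COEF,
        "participants": hormone_truth,
    }
    return df, truth


def simulate_trial_dataset(
    n_participants: int = 2,
    intensities: tuple[int, ...] = (30, 50, 70),
    n_trials_per_intensity: int = 1,
    pool_kwargs: dict | None = None,
    sample_rate: float = 2048.0,
    seed: int = 0,
    anovulatory_prop: float = 0.2,
):
    """Spike-level dataset: ramp trials with pool-simulated spike trains.

    The companion of :func:`simulate_cohort` for exercising the full feature
    pipeline (the cohort generator emits outcome tables directly). Returns
    ``(trials, spikes, trial_meta, participants)`` where ``spikes`` maps
    trial_id to the decomposed spike trains and the metadata frames use the
    same schemas the CSV readers consume.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    spikes: dict[str, list[SpikeTrain]] = {}
    trial_rows, participant_rows = [], []
    for ip in range(n_participants):
        pid = f"P{ip:03d}"
        mvc = float(rng.normal(30.0, 5.0))  # device units (e.g. Nm)
        anovulatory = bool(rng.random() < anovulatory_prop)
        lh_surge_day = None if anovulatory else int(13 + rng.integers(-2, 3))
        phase_order = list(rng.permutation(PHASES))
        for sess, ph in enumerate(phase_order, start=1):
            if ph == "EF":
                cycle_day = int(rng.integers(2, 5))
            elif ph == "LF":
                cycle_day = (lh_surge_day or 13) - int(rng.integers(1, 3))
            else:
                cycle_day = (lh_surge_day or 13) + int(rng.integers(7, 10))
            e2_med = HORMONE_MEDIANS["e2"][ph]
            p4_med = (
                P4_ANOVULATORY_MEDIAN
                if (ph == "ML" and anovulatory)
                else HORMONE_MEDIANS["p4"][ph]
            )
            e2 = float(np.exp(np.log(e2_med) + rng.normal(0, HORMONE_SIGMA["e2"])))
            p4 = float(np.exp(np.log(p4_med) + rng.normal(0, HORMONE_SIGMA["p4"])))
            participant_rows.append(
                {
                    "participant_id": pid,
                    "session": sess,
                    "phase": ph,
                    "cycle_day": cycle_day,
                    "e2": e2,
                    "p4": p4,
                    "lh_surge_day": lh_surge_day,
                }
            )
            for intensity in intensities:
                for k in range(n_trials_per_intensity):
                    trial_id = f"{pid}_s{sess}_{intensity}_{k}"
                    trial = make_torque_ramp(
                        float(intensity), rate_hz=sample_rate, trial_id=trial_id
                    )
                    trial.mvc_value = mvc
                    pool = default_pool(
                        seed=int(rng.integers(0, 2**31 - 1)),
                        threshold_range=(2.0, 0.6 * intensity),
                        **(pool_kwargs or {}),
                    )
                    trains = simulate_pool_trial(pool, trial, seed=pool.seed)
                    trials.append(trial)
                    spikes[trial_id] = trains
                    trial_rows.append(
                        {
                            "trial_id": trial_id,
                            "participant_id": pid,
                            "session": sess,
                            "phase": ph,
                            "intensity": intensity,
                            "mvc": mvc,
                            "sample_rate": sample_rate,
                            "ramp_up_s": trial.ramp_up_s,
                            "ramp_down_s": trial.ramp_down_s,
                        }
                    )
    return trials, spikes, pd.DataFrame(trial_rows), pd.DataFrame(participant_rows)


def cohort_sessions(df: pd.DataFrame) -> list[SessionContext]:
    """Per-participant-per-phase SessionContexts from a simulated cohort table."""
    meta = df.drop_duplicates(subset=["participant_id", "phase"])
    sessions = []
    for _, r in meta.iterrows():
        sessions.append(
            SessionContext(
                participant_id=r["participant_id"],
                session_number=int(r["session"]),
                phase=r["phase"],
                cycle_day=int(r["cycle_day"]),
                e2=float(r["e2"]),
                p4=float(r["p4"]),
                lh_surge_day=None if pd.isna(r["lh_surge_day"]) else int(r["lh_surge_day"]),
            )
        )
    return sessions
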