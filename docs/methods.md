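# Methods

This note documents the models, estimators, numerical choices and known
limitations of `mudra`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Discharge-rate features

A motor unit's instantaneous discharge rate (IDR) is the reciprocal of each
interspike interval, in pulses per second (pps). Each IDR value is
timestamped at the **later** spike of its interval — the causal convention:
the rate estimate becomes available when the second spike occurs. Units
contribute features only when they have at least 4 spikes spanning at least
1 s (the data are ramp contractions; anything shorter carries no usable rate
profile). Units below the floor are dropped and counted per reason in the
stage log.

IDR sequences are smoothed by ε-insensitive support vector regression with an
RBF kernel (scikit-learn). Inputs are the IDR timestamps (re-centered at the
first spike so the fit is translation-equivariant up to float round-off),
targets the IDR values, and the fitted function is evaluated on a grid at the
torque sample spacing clipped to [first spike, last spike]. Defaults:

| parameter | default | meaning |
|---|---|---|
| `C` | 10 | regularization; larger tracks ISI noise more |
| `epsilon` | 0.01 pps | insensitivity tube |
| `length_scale_s` | 2.5 s | RBF length scale; `gamma = 1/(2·ls²)` |
| `grid_hz` | 2048 | evaluation-grid rate (torque sampling rate) |

The defaults were fixed by two recovery requirements checked in the test
suite: a noiseless constant-rate train is reproduced essentially exactly, and
a noiseless linearly increasing rate (5→15 pps over 10 s) is recovered within
0.5 pps on the interior of the span (measured ≈ 0.1 pps). At gamma-ISI noise
with CV 0.15 the smoothed rate at a fixed interior instant has a standard
error of roughly 0.4–0.5 pps; this is the dominant noise term in everything
built on the smoothed profiles and cannot be reduced much by retuning —
longer length scales trade it against bias around the rate peak.

Recruitment and derecruitment thresholds are the torque (%MVC) **linearly
interpolated at the exact first/final spike instants**, not the nearest
sample. Initial and final rates are read from the smoothed profile at those
instants; peak rate is the profile maximum. The raw torque trace is
normalized by the trial MVC and, when requested, low-pass filtered with a
fifth-order Butterworth (default cutoff 10 Hz, config-exposed; the cutoff is
a free choice — ramp torque is quasi-static, so anything ≤ ~50 Hz is
equivalent for these features).

## PIC metrics

**ΔF (paired-unit hysteresis).** For test unit *t* and reporter *r*:
`ΔF = f_r(t_recruit) − f_r(t_derecruit)`, where `f_r` is the reporter's
smoothed rate (linear interpolation on its evaluation grid) and the two
instants are the test unit's first and final spikes. The derecruitment
instant is the final spike (not a torque crossing) — the spike train is the
observable. Pairs qualify only when all three field-standard criteria hold:

1. recruit delay ≥ 1 s (PIC of the reporter fully activated),
2. rate-rate Pearson correlation ≥ 0.7 between the two smoothed rates on a
   common grid over the joint active period (common synaptic drive),
3. reporter modulation ≥ 0.5 pps while the test unit is active.

The unit-wise ΔF is the arithmetic mean over eligible reporters; with zero
eligible reporters the value is undefined (NaN) and the unit is excluded from
ΔF models but counted in the yield diagnostics. Reporters are not consumed:
a unit may report for several tests and be a test itself (all-pairs design).

**Brace height.** Over [recruitment, instant of peak smoothed rate] both axes
are normalized to [0, 1]; the chord is then the unit-square diagonal, and the
signed orthogonal distance of the profile from it is `(y − x)/√2`. Brace
height is that distance at the point of maximal |deviation|, divided by the
altitude of the right triangle on the chord (`1/√2` in normalized units) and
expressed in percent — equivalently `100·(y − x)` at the extreme point.
Deviations **above** the chord (concave-down, saturating, PIC-like) are
positive. The geometry makes the measure invariant to affine rescaling of
either axis, which the tests verify directly.

**Acceleration/attenuation slopes.** The ascending limb (recruitment → peak
rate instant, in rate-vs-torque coordinates) is split at the abscissa of the
brace-height deviation maximum; ordinary least squares lines are fitted to
each segment (pps per %MVC). When |brace height| < 2 %rTri the profile is
treated as linear: one line is fitted and reported as both slopes. Segments
with fewer than 3 points leave that slope undefined.

## Cohort rules

Phases: early follicular (EF, menses, cycle day 2–4), late follicular (LF,
24–48 h before the LH surge), mid luteal (ML, 7–9 days after a positive
urinary LH test). Screening excludes a participant when mid-luteal serum
progesterone is **lower than** 12 nmol/L (exactly 12 passes — the comparison
is strict by the rule's wording) or when no positive ovulation test was
recorded in the testing cycle. LF window conformance is advisory only: LF is
verified retrospectively through hormones, not by a hard day rule. The
phase-by-session balance check is the Pearson chi-square test of independence
on the 3×3 participant count table (df = 4, no continuity correction).

## Mixed models

Both analysis stages use the weighted linear mixed model

    y = X β + u_participant + v_trial(participant) + ε,
    u ~ N(0, σ²_p),  v ~ N(0, σ²_t),  ε_i ~ N(0, σ²/w_i),

with w the motor-unit yield of the trial. statsmodels' MixedLM does not
accept observation weights, so the solver is implemented here: the deviance
is profiled over β and σ², leaving a 2-dimensional optimization over the
variance ratios (σ²_p/σ², σ²_t/σ²) in log space (Nelder-Mead); each
evaluation uses the Woodbury identity on per-participant blocks with cached
cross-products, so a 10,000-row fit takes a fraction of a second. ML and REML
criteria are both implemented; the tests verify agreement with statsmodels
MixedLM at unit weights to ~1e-4 and the algebraic identity that constant
weights reproduce the unweighted fit. Weights are rescaled to mean 1 before
fitting — the fit is mathematically invariant to that rescaling, but it keeps
the residual variance (and hence effect sizes) on the outcome scale.

**Phase models.** `Outcome ~ Phase + Intensity + Session +
RecruitmentThreshold + (1 | Participant/Trial)`, factors treatment-coded with
fixed level order (EF < LF < ML, 30 < 50 < 70, session 1 < 2 < 3; levels
absent from the data are dropped). The phase×intensity interaction enters the
final model only when a likelihood-ratio test against the additive model
rejects at α = 0.05; LRTs compare ML fits, final models are refit by REML.
Acceleration/attenuation slopes are fitted on the natural-log scale.

**Hormone models.** Estradiol and progesterone are natural-log transformed,
then split per participant into the mean across the three phases (between-
person level) and the phase deviation from it (within-person fluctuation);
mean + deviation reconstructs the log value exactly and deviations sum to
zero within participant. The model `Outcome ~ P4mean + P4within + E2mean +
E2within + Intensity + RecruitmentThreshold + (1 | Participant/Trial)`
estimates both components separately; a (within-hormone × intensity)
interaction is added only when the LRT improves fit. Outcomes can be z-scored
first so coefficients read in SD units; z-scoring leaves all slope
t-statistics unchanged (verified numerically). Hormones constant within every
participant make the within coefficients inestimable and raise an explicit
error.

**EMMs, contrasts, effect sizes.** Estimated marginal means average model
predictions over the other factors' levels with equal weight, covariates at
their data means; empty design cells raise an error listing them. Pairwise
contrasts use the Tukey studentized-range adjustment
(`p = SF_q(|t|·√2; k, n−p)`). Cohen's d divides a contrast by
`√(σ²_p + σ²_t + σ²)` — the model-based total SD. Inference is Wald/normal;
Satterthwaite-style degree-of-freedom corrections are deliberately not
chased, which makes the phase LRT mildly conservative on simulated nulls
(≈3–4 % rejection at α = 0.05 in the Monte-Carlo calibration the acceptance
script reruns).

**Collinearity.** Generalized variance inflation factors per fixed-effect
term via the determinant ratio on the correlation matrix of the non-intercept
design columns, scaled as `GVIF^(1/(2·df))`. Two predictors at correlation
0.8 give the closed-form VIF 1/(1−0.8²) = 2.778; orthogonal predictors give 1.

## Synthetic generator

**Pool/trial level.** Torque is a piecewise-linear triangle 0→target→0 %MVC.
Unit *i* (threshold θᵢ, ascending order = recruitment order) is active from
the ascending crossing of θᵢ to the descending crossing of θᵢ − δᵢ; δᵢ ≥ 0 is
the derecruitment hysteresis. Its instantaneous rate is
`baseline + gain·max(torque − θ, 0) + A·(1 − exp(−max(torque − θ, 0)/s))`;
the saturating term produces the concave-down onset that brace height
measures. ISIs are the reciprocal rate at the interval midpoint, multiplied
by gamma noise with CV 0.15 by default (CV 0 = deterministic). The first
spike sits exactly on the recruitment crossing and the last on the
derecruitment crossing (a final interval shorter than half the local ISI is
merged), so threshold estimates are exact up to interpolation and the
injected hysteresis maps cleanly through the pipeline. For **linear** rate
profiles (A = 0) and test instants inside every reporter's positive-drive
region, the ground-truth ΔF is exactly `gain · δ`; the bundled recovery pool
(reporters at 2/4/6 %MVC held active by large δ, one test unit at 14 %MVC
with δ = 4, gain 0.5) therefore has ground truth 2.0 pps. Defaults
(gain 0.25 pps/%MVC, baselines 10 − 0.12·θ pps, A = 12 pps, s = 2.5 %MVC)
give onion-skin peak ordering and brace heights around 35–40 %rTri on a 30 %
ramp.

**Cohort level.** 40 participants × 3 phases × 3 intensities with 2 trials
per intensity (the protocol's minimum), motor-unit yield per trial uniform
5–25 (yields are not published for this task; the range covers typical
dorsiflexor decompositions), outcome tables built directly from intensity
means + session (learning) effects + a recruitment-threshold association +
participant and trial random intercepts + unit-level noise, with injected
phase shifts and hormone coefficients on the log-hormone within/between
components. Hormone panels are lognormal with phase-specific medians (E2
peaks in LF, P4 in ML, in nmol/L on the scale of typical serum panels); a
configurable 20 % of participants are anovulatory (no LH surge, mid-luteal
P4 at follicular levels), matching the roughly one-in-five atypical-cycle
rate reported in regularly menstruating adults. The cohort generator emits
outcomes directly (it does not re-run spike simulation per trial); the
spike-level generator (`simulate_trial_dataset`) feeds the feature pipeline
and the two are consistent by construction, not by simulation.

(The outcome-level shortcut is what makes 300-replicate Monte-Carlo
calibration of the mixed models run in minutes rather than hours.)

**What the generator does not emulate.** Real decompositions carry
duplicate/merged units, editing errors, torque tracking error, unit-count
correlations with intensity, non-gamma ISI structure (doublets, synchrony),
and PIC dynamics beyond a static saturating drive term. Passing recovery
tests therefore demonstrates correctness of the estimators under the stated
generative assumptions, not robustness to decomposition artifacts.

## Numerical and design choices

* Smoothed-rate values "at" an instant are linear interpolation on the
  evaluation grid; smoothed rates are floored at 1e−6 pps (a discharging
  unit's rate is positive by definition; the floor only touches rare SVR
  edge undershoots).
* Rate-rate correlation uses the smoothed (not instantaneous) rates — the
  instantaneous series of two units have no common timestamps.
* Tie-breaks: the brace-height extreme is the first grid index of maximal
  |deviation|; the slope split point belongs to both segments.
* The LRT ladder and all thresholds (α = 0.05, eligibility 1 s / 0.7 /
  0.5 pps, |brace| < 2 %rTri linear fallback, 12 nmol/L screening) are
  config-exposed with the field-standard defaults.
* Monte-Carlo problem sizes in tests and the acceptance script: 40
  participants, 100 replicates for CI coverage, 200 for null calibration,
  20 seeded pools for noisy ΔF recovery — chosen as the smallest sizes at
  which the binomial/Monte-Carlo error is well inside the tolerances being
  checked.
* Random-number use is seeded everywhere (numpy `SeedSequence` spawning per
  unit); identical seed + config reproduces byte-identical pipeline CSVs.

## Known limitations

* Wald/normal inference for fixed effects (no Satterthwaite df); p-values on
  small cohorts are approximate and the phase LRT runs slightly conservative.
* The SVR smoother is a generic nonparametric choice; near the rate peak it
  biases the profile downward by a few tenths of a pps at the default length
  scale, which propagates into brace height (measured, not corrected).
* ΔF is undefined (by design) for units without eligible reporters; yield
  therefore varies between model weights and ΔF availability.
* The CLI pipeline fits models only when ≥ 2 participants with phase
  variation are present; singular fits are flagged, not silently accepted.
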