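"""Hierarchical statistics for motor unit outcomes.

Two stages mirror the study design:

1. **Phase models** — for each outcome (peak discharge rate, ΔF, brace
   height, log acceleration/attenuation slopes) a linear mixed model
   ``Outcome ~ Phase + Intensity + Session + RecruitmentThreshold +
   (1 | Participant/Trial)``, weighted by the motor-unit yield of each trial.
   A phase-by-intensity interaction enters the final model only when a
   log-likelihood ratio test against the additive model rejects (ML fits for
   the comparison, REML for the final fit). Estimated marginal means,
   Tukey-adjusted pairwise contrasts and model-based Cohen's d follow.

2. **Hormone models** — log-transformed estradiol and progesterone are split
   into a participant-level mean (between-person) and phase deviations from
   it (within-person), and enter
   ``Outcome ~ P4mean + P4within + E2mean + E2within + Intensity +
   RecruitmentThreshold + (1 | Participant/Trial)`` so that cycle-related
   fluctuations and stable individual differences are estimated separately.
   Outcomes may be z-scored first to express coefficients in SD units.

The weighted nested-random-intercept solver is implemented here directly:
the marginal covariance per participant is
``sigma2 * (W^-1 + g_p * 1 1' + g_t * blockdiag_J(trials))`` and the profiled
ML/REML deviance is minimized over the two variance ratios using the Woodbury
identity on each participant block (statsmodels' MixedLM does not accept the
observation weights this design requires; the two agree at unit weights).
Collinearity of fixed-effect terms is summarized by generalized variance
inflation factors (GVIFs), scaled as GVIF^(1/(2 df)).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("mudra")

PHASE_LEVELS = ["EF", "LF", "ML"]
INTENSITY_LEVELS = [30, 50, 70]
SESSION_LEVELS = [1, 2, 3]


class RankDeficiencyError(np.linalg.LinAlgError):
    """The fixed-effects design matrix is rank deficient."""


class SingularFitError(RuntimeError):
    """The mixed-model fit is singular or failed to converge."""


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Fixed-effects structure: treatment-coded factors, covariates, interactions.

    Factor levels are fixed and ordered (EF < LF < ML, 30 < 50 < 70,
    session 1 < 2 < 3); the first level is the reference. Interactions may
    pair two factors or a covariate with a factor.
    """

    outcome: str
    factors: dict[str, list] = field(default_factory=dict)
    covariates: list[str] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)

    def _expansions(self, get) -> dict[str, list[tuple[str, np.ndarray]]]:
        out: dict[str, list[tuple[str, np.ndarray]]] = {}
        for name, levels in self.factors.items():
            out[name] = [
                (f"{name}[T.{lv}]", np.asarray(get(name) == lv, dtype=float))
                for lv in levels[1:]
            ]
        for name in self.covariates:
            out[name] = [(name, np.asarray(get(name), dtype=float))]
        return out

    def _columns(self, get, n: int):
        exp = self._expansions(get)
        names = ["Intercept"]
        cols = [np.ones(n)]
        term_slices: dict[str, list[int]] = {"Intercept": [0]}
        for term in list(self.factors) + list(self.covariates):
            idx = []
            for nm, col in exp[term]:
                idx.append(len(cols))
                names.append(nm)
                cols.append(np.broadcast_to(col, (n,)).astype(float))
            term_slices[term] = idx
        for a, b in self.interactions:
            term = f"{a}:{b}"
            idx = []
            for (na, ca), (nb, cb) in itertools.product(exp[a], exp[b]):
                idx.append(len(cols))
                names.append(f"{na}:{nb}")
                cols.append(np.broadcast_to(ca * cb, (n,)).astype(float))
            term_slices[term] = idx
        return np.column_stack(cols), names, term_slices

    def build(self, df: pd.DataFrame):
        """Design matrix for a data frame. Checks declared factor levels."""
        for name, levels in self.factors.items():
            observed = set(df[name].unique())
            unknown = observed - set(levels)
            if unknown:
                raise ValueError(f"factor {name}: unexpected levels {sorted(unknown)}")
        X, names, term_slices = self._columns(lambda c: df[c].to_numpy(), len(df))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise RankDeficiencyError(
                f"design matrix for {self.outcome} is rank deficient "
                f"({X.shape[1]} columns)"
            )
        return X, names, term_slices

    def row(self, assignment: dict) -> np.ndarray:
        """Single design row for a virtual observation (used by EMMs)."""
        X, _, _ = self._columns(lambda c: np.asarray([assignment[c]]), 1)
        return X[0]


# ---------------------------------------------------------------------------
# weighted linear mixed model with nested random intercepts
# ---------------------------------------------------------------------------


@dataclass
class LMMFit:
    """A fitted weighted mixed model with participant and trial intercepts."""

    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    names: list[str]
    term_slices: dict[str, list[int]]
    var_participant: float
    var_trial: float
    var_residual: float
    loglike: float
    reml: bool
    n_obs: int
    n_params: int
    converged: bool
    boundary: bool
    spec: ModelSpec | None = None
    data: pd.DataFrame | None = None

    @property
    def total_sd(self) -> float:
        """sqrt(participant + trial + residual variance); Cohen's d denominator."""
        return float(np.sqrt(self.var_participant + self.var_trial + self.var_residual))

    @property
    def df_resid(self) -> int:
        return self.n_obs - self.n_params

    def wald_table(self) -> pd.DataFrame:
        z = self.beta / self.se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"term": self.names, "estimate": self.beta, "se": self.se, "z": z, "p": p}
        )

    def confint(self, level: float = 0.95) -> pd.DataFrame:
        q = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {
                "term": self.names,
                "lower": self.beta - q * self.se,
                "upper": self.beta + q * self.se,
            }
        )


class _NestedBlocks:
    """Per-participant cached cross-products for the profiled deviance.

    For participant i with T_i trials, Z_i = [1 | trial dummies] and the
    scaled marginal covariance is V0_i = W_i^-1 + g_p J + g_t blockdiag(J).
    All data-dependent products (Z'WZ, Z'WA, A'WA with A = [X | y]) are
    computed once; each deviance evaluation only factorizes a small
    (T_i + 1) x (T_i + 1) matrix per participant.
    """

    def __init__(self, X, y, w, participant, trial):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        w = np.asarray(w, float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        # weights are relative; scaling to mean 1 leaves the fit identical but
        # keeps the residual variance (and Cohen's d) on the outcome scale
        w = w / w.mean()
        _, p_idx = np.unique(participant, return_inverse=True)
        order = np.argsort(p_idx, kind="stable")
        X, y, w = X[order], y[order], w[order]
        p_idx = p_idx[order]
        trial = np.asarray(trial)[order]
        self.n, self.p = X.shape
        starts = np.searchsorted(p_idx, np.arange(p_idx.max() + 2))
        self.blocks = []
        self.sum_log_w = float(np.log(w).sum())
        for i in range(len(starts) - 1):
            s, e = starts[i], starts[i + 1]
            _, t_idx = np.unique(trial[s:e], return_inverse=True)
            r = t_idx.max() + 2  # participant intercept + trial dummies
            Z = np.zeros((e - s, r))
            Z[:, 0] = 1.0
            Z[np.arange(e - s), 1 + t_idx] = 1.0
            A = np.column_stack([X[s:e], y[s:e]])
            WA = w[s:e, None] * A
            self.blocks.append(
                {
                    "r": r,
                    "ZtWZ": Z.T @ (w[s:e, None] * Z),
                    "ZtWA": Z.T @ WA,
                    "AtWA": A.T @ WA,
                }
            )

    def profiled(self, theta):
        """beta-hat, weighted RSS, log|V0| and X'V0^-1 X at variance ratios exp(theta)."""
        g_p, g_t = np.exp(theta)
        p = self.p
        AtVA = np.zeros((p + 1, p + 1))
        logdet = -self.sum_log_w
        for b in self.blocks:
            r = b["r"]
            D = np.concatenate([[g_p], np.full(r - 1, g_t)])
            M = np.diag(1.0 / D) + b["ZtWZ"]
            c, low = np.linalg.cholesky(M), True
            logdet += 2 * np.log(np.diag(c)).sum() + np.log(D).sum()
            tmp = np.linalg.solve(M, b["ZtWA"])
            AtVA += b["AtWA"] - b["ZtWA"].T @ tmp
        XtVX = AtVA[:-1, :-1]
        XtVy = AtVA[:-1, -1]
        ytVy = AtVA[-1, -1]
        beta = np.linalg.solve(XtVX, XtVy)
        rss = float(ytVy - XtVy @ beta)
        return beta, rss, logdet, XtVX

    def neg2ll(self, theta, reml: bool):
        beta, rss, logdet, XtVX = self.profiled(theta)
        n, p = self.n, self.p
        if reml:
            s2 = rss / (n - p)
            _, logdetX = np.linalg.slogdet(XtVX)
            return (n - p) * np.log(2 * np.pi * s2) + logdet + logdetX + (n - p)
        s2 = rss / n
        return n * np.log(2 * np.pi * s2) + logdet + n


def fit_weighted_lmm(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    participant: np.ndarray,
    trial: np.ndarray,
    names: list[str] | None = None,
    term_slices: dict | None = None,
    reml: bool = True,
) -> LMMFit:
    """Fit the weighted LMM with random intercepts for participant and
    trial-within-participant by profiled ML/REML.

    Raises
    ------
    RankDeficiencyError on a rank-deficient design; SingularFitError when the
    optimizer fails. A variance component estimated at (numerically) zero is
    reported via ``boundary=True`` rather than an exception.
    """
    X = np.asarray(X, float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("rank-deficient fixed-effects design")
    blocks = _NestedBlocks(X, y, weights, participant, trial)
    res = optimize.minimize(
        lambda th: blocks.neg2ll(th, reml),
        x0=np.array([0.0, 0.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 500},
    )
    if not np.isfinite(res.fun):
        raise SingularFitError("mixed-model deviance not finite at optimum")
    theta = res.x
    beta, rss, logdet, XtVX = blocks.profiled(theta)
    n, p = blocks.n, blocks.p
    s2 = rss / ((n - p) if reml else n)
    g_p, g_t = np.exp(theta)
    cov_beta = s2 * np.linalg.inv(XtVX)
    return LMMFit(
        beta=beta,
        se=np.sqrt(np.diag(cov_beta)),
        cov_beta=cov_beta,
        names=names or [f"x{i}" for i in range(p)],
        term_slices=term_slices or {},
        var_participant=float(g_p * s2),
        var_trial=float(g_t * s2),
        var_residual=float(s2),
        loglike=float(-0.5 * blocks.neg2ll(theta, reml)),
        reml=reml,
        n_obs=n,
        n_params=p,
        converged=bool(res.success),
        boundary=bool(min(g_p, g_t) < 1e-6),
    )


def likelihood_ratio_test(fit0: LMMFit, fit1: LMMFit) -> tuple[float, int, float]:
    """LRT between nested ML fits (fit1 the larger model). Returns (chi2, df, p)."""
    if fit0.reml or fit1.reml:
        raise ValueError("likelihood ratio tests require ML (reml=False) fits")
    df = fit1.n_params - fit0.n_params
    if df <= 0:
        raise ValueError("fit1 must have more fixed-effect parameters than fit0")
    lr = max(0.0, 2.0 * (fit1.loglike - fit0.loglike))
    return lr, df, float(stats.chi2.sf(lr, df))


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def decompose_hormones(panel: pd.DataFrame) -> pd.DataFrame:
    """Within/between decomposition of log-transformed hormones.

    Expects one row per participant per phase with positive ``e2`` and ``p4``
    (nmol/L). Adds natural-log columns, the participant-level mean across the
    three phases (between-person component) and the phase deviation from that
    mean (within-person component). mean + within reconstructs the log value
    exactly and the within components of each participant sum to zero.
    """
    panel = panel.copy()
    for hormone in ("e2", "p4"):
        bad = panel[panel[hormone] <= 0]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                f"nonpositive {hormone} for participant {row['participant_id']} "
                f"phase {row.get('phase', '?')}"
            )
        panel[f"log_{hormone}"] = np.log(panel[hormone].astype(float))
        grp = panel.groupby("participant_id")[f"log_{hormone}"]
        panel[f"{hormone}_mean"] = grp.transform("mean")
        panel[f"{hormone}_within"] = panel[f"log_{hormone}"] - panel[f"{hormone}_mean"]
    counts = panel.groupby("participant_id")["phase"].nunique()
    if (counts != 3).any():
        raise ValueError(
            f"expected 3 phases per participant; offending: "
            f"{list(counts[counts != 3].index)}"
        )
    return panel


def standardize_outcomes(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Z-score outcome columns over the analysis set (ignoring NaN)."""
    out = df.copy()
    for col in columns:
        vals = out[col].astype(float)
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"outcome {col} has zero variance; cannot standardize")
        out[col] = (vals - vals.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# model fitting ladders
# ---------------------------------------------------------------------------


@dataclass
class ModelLadderResult:
    """Final REML fit plus the ML model-selection trail."""

    fit: LMMFit
    spec: ModelSpec
    data: pd.DataFrame
    lrt_interaction: tuple[float, int, float] | None
    interaction_included: bool
    lrt_terms: dict[str, tuple[float, int, float]] = field(default_factory=dict)


def _fit_spec(spec: ModelSpec, df: pd.DataFrame, weights_col: str, reml: bool) -> LMMFit:
    X, names, slices = spec.build(df)
    fit = fit_weighted_lmm(
        X,
        df[spec.outcome].to_numpy(float),
        df[weights_col].to_numpy(float),
        df["participant_id"].to_numpy(),
        df["trial_id"].to_numpy(),
        names=names,
        term_slices=slices,
        reml=reml,
    )
    fit.spec = spec
    fit.data = df
    return fit


def fit_phase_model(
    data: pd.DataFrame,
    outcome: str,
    weights_col: str = "yield",
    include_session: bool = True,
    include_rt: bool = True,
    log_outcome: bool = False,
    interaction: str = "lrt",
    alpha: float = 0.05,
    term_lrts: tuple[str, ...] = ("phase", "session"),
) -> ModelLadderResult:
    """Phase/intensity mixed model for one motor unit outcome.

    ``interaction`` is one of ``"lrt"`` (include phase-by-intensity when a
    likelihood ratio test at ``alpha`` rejects the additive model), ``"always"``
    or ``"never"``. Slope outcomes are fitted on the natural-log scale via
    ``log_outcome=True``. Rows with missing outcome are dropped. ``term_lrts``
    selects which single-term likelihood ratio tests (dropping the term from
    the additive ML model) are reported.
    """
    df = data.dropna(subset=[outcome]).copy()
    if df["participant_id"].nunique() < 2:
        raise ValueError("phase model needs >=2 participants")
    if log_outcome:
        if (df[outcome] <= 0).any():
            raise ValueError(f"log transform of {outcome}: nonpositive values present")
        df[outcome] = np.log(df[outcome].astype(float))
    factors = {}
    for name, levels in (
        ("phase", PHASE_LEVELS),
        ("intensity", INTENSITY_LEVELS),
        ("session", SESSION_LEVELS if include_session else []),
    ):
        observed = [lv for lv in levels if (df[name] == lv).any()] if levels else []
        if len(observed) >= 2:
            factors[name] = observed
    if "phase" not in factors:
        raise ValueError("phase model needs >=2 observed phase levels")
    covariates = ["recruitment_threshold"] if include_rt else []
    additive = ModelSpec(outcome, dict(factors), list(covariates))
    inter = ModelSpec(
        outcome, dict(factors), list(covariates), interactions=[("phase", "intensity")]
    )

    lrt_int = None
    if "intensity" not in factors:
        interaction = "never"
    use_inter = interaction == "always"
    if interaction == "lrt":
        m0 = _fit_spec(additive, df, weights_col, reml=False)
        m1 = _fit_spec(inter, df, weights_col, reml=False)
        lrt_int = likelihood_ratio_test(m0, m1)
        use_inter = lrt_int[2] < alpha

    # term-wise LRTs: drop one term from the additive ML model
    lrt_terms = {}
    wanted = [t for t in term_lrts if t in factors]
    if wanted:
        base_ml = _fit_spec(additive, df, weights_col, reml=False)
        for term in wanted:
            reduced = ModelSpec(
                outcome,
                {k: v for k, v in factors.items() if k != term},
                list(covariates),
            )
            lrt_terms[term] = likelihood_ratio_test(
                _fit_spec(reduced, df, weights_col, reml=False), base_ml
            )

    final_spec = inter if use_inter else additive
    fit = _fit_spec(final_spec, df, weights_col, reml=True)
    if fit.boundary:
        logger.warning(
            "phase model for %s: a variance component is at the boundary "
            "(participant %.3g, trial %.3g)", outcome, fit.var_participant, fit.var_trial,
        )
    return ModelLadderResult(
        fit=fit,
        spec=final_spec,
        data=df,
        lrt_interaction=lrt_int,
        interaction_included=use_inter,
        lrt_terms=lrt_terms,
    )


def fit_hormone_model(
    data: pd.DataFrame,
    outcome: str,
    weights_col: str = "yield",
    include_rt: bool = True,
    log_outcome: bool = False,
    interaction: str = "lrt",
    alpha: float = 0.05,
) -> ModelLadderResult:
    """Within/between hormone mixed model for one outcome.

    Expects the within/between columns produced by :func:`decompose_hormones`
    merged onto the unit-level table. A hormone-by-intensity interaction (both
    within-person hormone terms) is added only when the LRT improves fit.
    """
    df = data.dropna(subset=[outcome]).copy()
    for col in ("p4_within", "e2_within"):
        if df[col].abs().max() < 1e-12:
            raise ValueError(
                f"{col} has zero variance (hormones constant within participants); "
                "within-person coefficients are inestimable"
            )
    if log_outcome:
        if (df[outcome] <= 0).any():
            raise ValueError(f"log transform of {outcome}: nonpositive values present")
        df[outcome] = np.log(df[outcome].astype(float))
    covariates = ["p4_mean", "p4_within", "e2_mean", "e2_within"]
    if include_rt:
        covariates.append("recruitment_threshold")
    observed = [lv for lv in INTENSITY_LEVELS if (df["intensity"] == lv).any()]
    factors = {"intensity": observed} if len(observed) >= 2 else {}
    base = ModelSpec(outcome, dict(factors), list(covariates))
    inter = ModelSpec(
        outcome,
        dict(factors),
        list(covariates),
        interactions=[("p4_within", "intensity"), ("e2_within", "intensity")]
        if factors
        else [],
    )
    lrt_int = None
    if not factors:
        interaction = "never"
    use_inter = interaction == "always"
    if interaction == "lrt":
        m0 = _fit_spec(base, df, weights_col, reml=False)
        m1 = _fit_spec(inter, df, weights_col, reml=False)
        lrt_int = likelihood_ratio_test(m0, m1)
        use_inter = lrt_int[2] < alpha
    final_spec = inter if use_inter else base
    fit = _fit_spec(final_spec, df, weights_col, reml=True)
    return ModelLadderResult(
        fit=fit,
        spec=final_spec,
        data=df,
        lrt_interaction=lrt_int,
        interaction_included=use_inter,
    )


# ---------------------------------------------------------------------------
# estimated marginal means, contrasts, effect sizes
# ---------------------------------------------------------------------------


def _reference_rows(fit: LMMFit, fixed: dict) -> np.ndarray:
    """Average design row over the factor grid, with some levels pinned.

    Covariates sit at their data means; unpinned factors are averaged with
    equal weight over their observed levels.
    """
    spec, df = fit.spec, fit.data
    cov_means = {}
    for c in spec.covariates:
        cov_means[c] = float(df[c].mean())
    free = {f: lv for f, lv in spec.factors.items() if f not in fixed}
    combos = list(itertools.product(*free.values())) or [()]
    rows = []
    for combo in combos:
        assignment = dict(cov_means)
        assignment.update(fixed)
        assignment.update(dict(zip(free.keys(), combo)))
        rows.append(spec.row(assignment))
    return np.mean(rows, axis=0)


def _check_cells(fit: LMMFit) -> None:
    spec, df = fit.spec, fit.data
    if not spec.factors:
        return
    grid = list(itertools.product(*spec.factors.values()))
    observed = set(map(tuple, df[list(spec.factors)].itertuples(index=False, name=None)))
    missing = [g for g in grid if g not in observed]
    if missing:
        raise ValueError(f"empty design cells for {list(spec.factors)}: {missing}")


def emm_contrasts(
    fit: LMMFit, factor: str, by: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimated marginal means of ``factor`` and Tukey-adjusted pairwise contrasts.

    EMMs average the model predictions over the other factors' levels with
    covariates at their means. When ``by`` is given, simple-effect contrasts
    are computed within each level of that factor (appropriate when an
    interaction is present). Cohen's d divides each contrast by the square
    root of the summed random-effect and residual variances.
    """
    if fit.spec is None or fit.data is None:
        raise ValueError("fit carries no model spec/data; refit via the ladder helpers")
    if factor not in fit.spec.factors:
        raise ValueError(f"{factor!r} is not a factor of this model")
    _check_cells(fit)
    levels = fit.spec.factors[factor]
    by_levels = fit.spec.factors[by] if by else [None]
    k = len(levels)
    df_resid = fit.df_resid

    emm_rows, con_rows = [], []
    for bl in by_levels:
        pinned_base = {} if by is None else {by: bl}
        L = {lv: _reference_rows(fit, {**pinned_base, factor: lv}) for lv in levels}
        for lv in levels:
            est = float(L[lv] @ fit.beta)
            se = float(np.sqrt(L[lv] @ fit.cov_beta @ L[lv]))
            emm_rows.append(
                {
                    "factor": factor,
                    "level": lv,
                    **({} if by is None else {by: bl}),
                    "emmean": est,
                    "se": se,
                    "lower": est - 1.96 * se,
                    "upper": est + 1.96 * se,
                }
            )
        for a, b in itertools.combinations(levels, 2):
            c = L[b] - L[a]
            est = float(c @ fit.beta)
            se = float(np.sqrt(c @ fit.cov_beta @ c))
            t = est / se
            p_tukey = float(
                stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df_resid)
            )
            con_rows.append(
                {
                    "contrast": f"{b} - {a}",
                    **({} if by is None else {by: bl}),
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p_tukey": p_tukey,
                    "cohens_d": est / fit.total_sd,
                }
            )
    return pd.DataFrame(emm_rows), pd.DataFrame(con_rows)


# ---------------------------------------------------------------------------
# collinearity diagnostics
# ---------------------------------------------------------------------------


def collinearity_diagnostics(fit_or_X, names=None, term_slices=None) -> pd.DataFrame:
    """Scaled generalized variance inflation factors per fixed-effect term.

    GVIF_j = det(R_jj) det(R_-j-j) / det(R) on the correlation matrix of the
    non-intercept design columns; the scaled value GVIF^(1/(2 df)) is
    comparable across terms of different df. Perfectly collinear terms are
    reported as infinite.
    """
    if isinstance(fit_or_X, LMMFit):
        if fit_or_X.spec is None or fit_or_X.data is None:
            raise ValueError("fit carries no model spec/data")
        X, names, term_slices = fit_or_X.spec.build(fit_or_X.data)
    else:
        X = np.asarray(fit_or_X, float)
        if names is None or term_slices is None:
            raise ValueError("names and term_slices required with a raw design matrix")
    keep = [i for i in range(X.shape[1]) if names[i] != "Intercept"]
    if len(keep) < 2:
        raise ValueError("GVIFs need >=2 non-intercept fixed-effect columns")
    sub = X[:, keep]
    remap = {orig: new for new, orig in enumerate(keep)}
    R = np.corrcoef(sub, rowvar=False)
    det_R = np.linalg.det(R)
    rows = []
    for term, idx in term_slices.items():
        if term == "Intercept" or not idx:
            continue
        j = [remap[i] for i in idx]
        other = [i for i in range(len(keep)) if i not in j]
        if det_R <= 1e-12:
            gvif = float("inf")
        else:
            det_j = np.linalg.det(R[np.ix_(j, j)]) if len(j) > 1 else R[j[0], j[0]]
            det_o = np.linalg.det(R[np.ix_(other, other)]) if len(other) > 1 else (
                R[other[0], other[0]] if other else 1.0
            )
            gvif = float(det_j * det_o / det_R)
        dfree = len(j)
        rows.append(
            {
                "term": term,
                "df": dfree,
                "gvif": gvif,
                "scaled_gvif": gvif ** (1.0 / (2 * dfree)) if np.isfinite(gvif) else float("inf"),
            }
        )
    return pd.DataFrame(rows)
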