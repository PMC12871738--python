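"""Menstrual-cycle phase definitions, hormone-based screening, session balance.

Participants are tested once in each of three hormonally distinct phases:
early follicular (EF, during menses, cycle day 2-4), late follicular (LF,
24-48 h before the luteinizing-hormone surge) and mid luteal (ML, 7-9 days
after a positive urinary LH test). Serum hormone concentrations confirm the
phase retrospectively: a participant is excluded when mid-luteal progesterone
falls below 12 nmol/L or no positive ovulation test was recorded in the
testing cycle. A chi-square test of independence checks that phases were
balanced across session numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PHASES = ("EF", "LF", "ML")
#: ML serum progesterone below this (nmol/L) excludes the participant
P4_LUTEAL_THRESHOLD_NMOL = 12.0
EF_WINDOW_DAYS = (2, 4)
ML_WINDOW_DAYS_POST_SURGE = (7, 9)
LF_WINDOW_DAYS_PRE_SURGE = (1, 2)  # visit 24-48 h before the LH surge


@dataclass
class SessionContext:
    """One testing session of one participant, with phase and hormone panel."""

    participant_id: str
    session_number: int  # 1, 2 or 3
    phase: str  # EF, LF or ML
    cycle_day: int
    e2: float  # serum estradiol, nmol/L
    p4: float  # serum progesterone, nmol/L
    lh_surge_day: int | None = None  # cycle day of positive LH test, if any

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if self.e2 <= 0 or self.p4 <= 0:
            raise ValueError(
                f"participant {self.participant_id} {self.phase}: hormone "
                "concentrations must be positive"
            )


@dataclass
class ScreeningResult:
    participant_id: str
    include: bool
    reasons: list[str]


def screen_participant(sessions: list[SessionContext]) -> ScreeningResult:
    """Hormone-based inclusion screening over a participant's three sessions.

    Excluded iff mid-luteal progesterone is lower than 12 nmol/L (a value of
    exactly 12 passes) or no positive ovulation (LH) test was recorded during
    the testing cycle. Order of the session list is irrelevant.
    """
    if not sessions:
        raise ValueError("no sessions provided")
    pid = sessions[0].participant_id
    by_phase = {s.phase: s for s in sessions}
    if len(by_phase) != len(sessions) or set(by_phase) != set(PHASES):
        raise ValueError(
            f"participant {pid}: expected exactly one session per phase "
            f"{PHASES}, got {sorted(s.phase for s in sessions)}"
        )
    ml = by_phase["ML"]
    reasons = []
    if ml.p4 < P4_LUTEAL_THRESHOLD_NMOL:
        reasons.append(
            f"luteal progesterone below threshold ({ml.p4:.1f} < "
            f"{P4_LUTEAL_THRESHOLD_NMOL} nmol/L)"
        )
    if not any(s.lh_surge_day is not None for s in sessions):
        reasons.append("no positive ovulation test during the testing cycle")
    return ScreeningResult(pid, include=not reasons, reasons=reasons)


def phase_window_check(ctx: SessionContext) -> tuple[bool, str]:
    """Diagnostic check that a session fell in its phase's scheduling window.

    EF must fall on cycle day 2-4; ML 7-9 days after the positive LH test.
    LF conformance is advisory (verified retrospectively via hormones): when
    the surge day is known the visit should precede it by 1-2 days, otherwise
    the check passes with a note.
    """
    if ctx.phase == "EF":
        lo, hi = EF_WINDOW_DAYS
        ok = lo <= ctx.cycle_day <= hi
        return ok, f"EF visit on cycle day {ctx.cycle_day} (window {lo}-{hi})"
    if ctx.phase == "ML":
        if ctx.lh_surge_day is None:
            return False, "ML visit without a recorded LH surge day"
        lo, hi = ML_WINDOW_DAYS_POST_SURGE
        delta = ctx.cycle_day - ctx.lh_surge_day
        ok = lo <= delta <= hi
        return ok, f"ML visit {delta} days post LH surge (window {lo}-{hi})"
    # LF
    if ctx.lh_surge_day is None:
        return True, "LF visit; surge day unknown, conformance advisory"
    lo, hi = LF_WINDOW_DAYS_PRE_SURGE
    delta = ctx.lh_surge_day - ctx.cycle_day
    ok = lo <= delta <= hi
    return ok, f"LF visit {delta} days before LH surge (window {lo}-{hi})"


def session_balance_test(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test of phase x session independence (df = 4).

    Parameters
    ----------
    table : 3x3 array of participant counts, phases in rows, sessions in columns.

    Returns
    -------
    (chi2, df, p)
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (3, 3):
        raise ValueError(f"expected a 3x3 phase-by-session table, got shape {table.shape}")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("table must contain nonnegative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def phase_session_table(sessions: list[SessionContext]) -> pd.DataFrame:
    """Count participants in each phase at each session number."""
    df = pd.DataFrame(
        {"phase": [s.phase for s in sessions], "session": [s.session_number for s in sessions]}
    )
    table = pd.crosstab(df["phase"], df["session"]).reindex(
        index=list(PHASES), columns=[1, 2, 3], fill_value=0
    )
    return table
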