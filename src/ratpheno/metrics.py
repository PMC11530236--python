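"""Per-rat behavioral metrics: escalation, progressive ratio, shock, irritability.

Four behaviors summarise each animal's run through the protocol:

* **escalation** — mean daily infusions over the last three 6-h long-access
  (LgA) sessions, after single-gap imputation;
* **motivation** — infusions earned under the progressive-ratio (PR)
  schedule after LgA, plus the breakpoint (last completed response
  requirement before a 60-min lapse);
* **compulsivity** — infusions earned in a 1-h session in which 30% of
  rewards are paired with a 0.3 mA footshock, against the matched 1-h
  preshock session;
* **irritability** — observer-averaged aggressive + defensive bottle-brush
  scores, withdrawal minus baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import StudyTables, impute_missing_sessions

__all__ = [
    "PR_SCHEDULE",
    "pr_requirement",
    "pr_schedule",
    "compute_breakpoint",
    "escalation_summary",
    "hourly_rate",
    "irritability_scores",
    "irritability_delta",
    "shock_suppression",
    "summarize_behavior",
    "BEHAVIOR_COLUMNS",
]

#: The printed response-requirement sequence; authoritative for j = 1..18.
PR_SCHEDULE = (1, 2, 4, 6, 9, 12, 15, 20, 25, 32, 40, 50, 62, 77, 95, 118, 145, 178)

#: Minutes without a completed ratio that end a PR session.
PR_LAPSE_MINUTES = 60.0


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def pr_requirement(j: int) -> int:
    """Response requirement for the *j*-th reward of the PR schedule.

    The printed 18-term table is authoritative for j <= 18; beyond it the
    generating form ``round(5·e^(0.2 j)) − 5`` (round half away from zero)
    extrapolates the schedule.
    """
    j = int(j)
    if j < 1:
        raise ValueError(f"PR reward index must be >= 1, got {j}")
    if j <= len(PR_SCHEDULE):
        return PR_SCHEDULE[j - 1]
    return _round_half_away(5.0 * math.exp(0.2 * j)) - 5


def pr_schedule(n: int) -> list[int]:
    """First *n* response requirements of the PR schedule."""
    return [pr_requirement(j) for j in range(1, n + 1)]


# The closed form must regenerate the printed table exactly; the table wins on
# any mismatch, so a discrepancy here is a packaging bug worth failing loudly.
_formula = [_round_half_away(5.0 * math.exp(0.2 * j)) - 5 for j in range(1, 19)]
if tuple(_formula) != PR_SCHEDULE:  # pragma: no cover
    raise RuntimeError("PR requirement formula does not reproduce the printed schedule")
del _formula


def compute_breakpoint(
    reward_times: Sequence[float], session_minutes: float = 360.0
) -> tuple[int, int]:
    """Apply the 60-min lapse rule to a PR session's reward-completion times.

    Scanning completions in order, the session terminates at the first gap of
    60 min or more between consecutive completions — including the gap from
    session start to the first completion and from the last completion to the
    scheduled session end. Returns ``(rewards_counted, breakpoint)`` where the
    breakpoint is the requirement of the last counted reward (0 if none).
    """
    times = np.asarray(reward_times, dtype=float)
    if times.size and (np.any(np.diff(times) <= 0)):
        raise ValueError("reward times must be strictly increasing")
    if times.size and (times[0] < 0 or times[-1] > session_minutes):
        raise ValueError("reward times must lie within the session")
    n = 0
    previous = 0.0  # session start counts toward the lapse rule
    for t in times:
        if t - previous >= PR_LAPSE_MINUTES:
            break
        n += 1
        previous = t
    return n, (pr_requirement(n) if n > 0 else 0)


def escalation_summary(lga_daily_totals: Sequence[float],
                       missing: Sequence[bool] | None = None) -> float:
    """Mean intake over the last three LgA sessions (days 12-14 of 14).

    Isolated gaps are imputed first; an unresolved gap among the last three
    days leaves the summary undefined (NaN).
    """
    completed, _, unresolved = impute_missing_sessions(lga_daily_totals, missing)
    if completed.size < 3:
        raise ValueError("need at least 3 LgA sessions for an escalation summary")
    last3 = completed[-3:]
    if unresolved[-3:].any() or np.isnan(last3).any():
        return float("nan")
    return float(np.mean(last3))


def hourly_rate(infusions: float, duration_h: float) -> float:
    """Infusions per hour for one session."""
    if duration_h <= 0:
        raise ValueError(f"session duration must be positive, got {duration_h}")
    return float(infusions) / float(duration_h)


def irritability_scores(aggressive: Sequence[float],
                        defensive: Sequence[float]) -> tuple[float, float, float]:
    """Observer-averaged bottle-brush scores for one assay.

    Each observer reports summed aggressive and defensive responses over the
    ten trials; scores are averaged over observers and the total is their sum.
    Returns ``(aggressive, defensive, total)``.
    """
    agg = np.asarray(aggressive, dtype=float)
    dfn = np.asarray(defensive, dtype=float)
    if agg.size == 0 or dfn.size == 0:
        raise ValueError("at least one observer is required")
    if (agg < 0).any() or (dfn < 0).any():
        raise ValueError("observer scores must be >= 0")
    a, d = float(agg.mean()), float(dfn.mean())
    return a, d, a + d


@dataclass(frozen=True)
class IrritabilityDelta:
    aggressive: float
    defensive: float
    total: float


def irritability_delta(baseline: pd.Series | dict, withdrawal: pd.Series | dict) -> IrritabilityDelta:
    """Withdrawal-minus-baseline irritability, componentwise.

    Both records must belong to the same rat (checked when ``rat_id`` is
    present on both).
    """
    b, w = dict(baseline), dict(withdrawal)
    if "rat_id" in b and "rat_id" in w and b["rat_id"] != w["rat_id"]:
        raise ValueError(
            f"records belong to different rats: {b['rat_id']!r} vs {w['rat_id']!r}"
        )
    return IrritabilityDelta(
        aggressive=float(w["aggressive"]) - float(b["aggressive"]),
        defensive=float(w["defensive"]) - float(b["defensive"]),
        total=float(w["total"]) - float(b["total"]),
    )


def shock_suppression(preshock_infusions: float,
                      shock_infusions: float) -> tuple[float, float]:
    """Suppression of responding by contingent footshock.

    Returns ``(difference, ratio)`` = (preshock − shock, shock/preshock); the
    ratio is NaN when the preshock count is zero.
    """
    pre, shock = float(preshock_infusions), float(shock_infusions)
    if pre < 0 or shock < 0:
        raise ValueError("infusion counts must be >= 0")
    ratio = shock / pre if pre > 0 else float("nan")
    return pre - shock, ratio


BEHAVIOR_COLUMNS = [
    "rat_id",
    "esc_mean_last3",
    "pr_rewards_post_lga",
    "pr_breakpoint",
    "preshock_infusions",
    "shock_infusions",
    "irritability_delta_total",
    "irritability_delta_aggressive",
    "irritability_delta_defensive",
]


def _impute_isolated_gaps(matrix: np.ndarray) -> np.ndarray:
    """Row-wise two-neighbour imputation on a rats × days matrix.

    Vectorised form of :func:`~ratpheno.data_model.impute_missing_sessions`:
    isolated interior NaNs become the mean of their neighbours; consecutive
    or terminal gaps stay NaN.
    """
    out = matrix.copy()
    gap = np.isnan(out)
    if gap.any() and out.shape[1] >= 3:
        interior = gap[:, 1:-1] & ~gap[:, :-2] & ~gap[:, 2:]
        fill = 0.5 * (out[:, :-2] + out[:, 2:])
        out[:, 1:-1] = np.where(interior, fill, out[:, 1:-1])
    return out


def _phase_pivot(sessions: pd.DataFrame, phase: str,
                 index: pd.Index) -> pd.DataFrame:
    sub = sessions[(sessions["phase"] == phase) & (~sessions["missing"])]
    wide = sub.pivot_table(index="rat_id", columns="day_index",
                           values="infusions", aggfunc="first")
    return wide.reindex(index)


def summarize_behavior(tables: StudyTables, motivation_session: int = 2) -> pd.DataFrame:
    """One :data:`BEHAVIOR_COLUMNS` row per non-excluded cocaine rat.

    ``motivation_session`` selects which PR test feeds the motivation metric:
    2 is the post-LgA test preceding the shock session (the default), 3 the
    one following it. Metrics whose inputs are absent come out NaN and
    propagate as missing downstream.
    """
    if motivation_session not in (2, 3):
        raise ValueError("motivation_session must be 2 (pre-shock) or 3 (post-shock)")
    rats, sessions, irritability = tables
    cocaine = rats[(rats["group"] == "cocaine") & (~rats["excluded"])]
    ids = pd.Index(cocaine["rat_id"], name="rat_id")

    # escalation: 14-day LgA grid, imputation, then the last-3-day mean
    lga = _phase_pivot(sessions, "LgA", ids).reindex(columns=range(1, 15))
    completed = _impute_isolated_gaps(lga.to_numpy(float))
    esc = completed[:, -3:].mean(axis=1)  # NaN if any of days 12-14 unresolved

    pr = _phase_pivot(sessions, "PR", ids)
    pr_rewards = pr[motivation_session].to_numpy(float) \
        if motivation_session in pr.columns else np.full(len(ids), np.nan)
    bp = np.array([
        float("nan") if np.isnan(r) else float(pr_requirement(int(r))) if r > 0
        else 0.0
        for r in pr_rewards
    ])

    def single_day(phase):
        wide = _phase_pivot(sessions, phase, ids)
        return wide[1].to_numpy(float) if 1 in wide.columns \
            else np.full(len(ids), np.nan)

    pre = single_day("PreShock")
    shock = single_day("Shock")

    deltas = {}
    irr_wide = irritability.pivot_table(
        index="rat_id", columns="timepoint",
        values=["total", "aggressive", "defensive"], aggfunc="first")
    for comp in ("total", "aggressive", "defensive"):
        if ("withdrawal" in irritability["timepoint"].values
                and "baseline" in irritability["timepoint"].values):
            col = (irr_wide[(comp, "withdrawal")]
                   - irr_wide[(comp, "baseline")]).reindex(ids)
            deltas[comp] = col.to_numpy(float)
        else:
            deltas[comp] = np.full(len(ids), np.nan)

    return pd.DataFrame({
        "rat_id": ids.to_numpy(),
        "esc_mean_last3": esc,
        "pr_rewards_post_lga": pr_rewards,
        "pr_breakpoint": bp,
        "preshock_infusions": pre,
        "shock_infusions": shock,
        "irritability_delta_total": deltas["total"],
        "irritability_delta_aggressive": deltas["aggressive"],
        "irritability_delta_defensive": deltas["defensive"],
    })
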