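"""Tidy study tables, CSV ingestion/emission, validation, and session imputation.

The study is represented as three long-format tables, one row per record:

``rats``
    one row per animal — ``rat_id``, ``sex`` (F/M), ``cohort`` (1..n),
    ``group`` (cocaine/naive), ``excluded`` (catheter-patency failure).
``sessions``
    one row per operant self-administration session — ``rat_id``, ``phase``
    (ShA/LgA/PreShock/Shock/PR), ``day_index`` (1-based within phase),
    ``duration_h``, ``infusions``, ``hour1_infusions``, ``active_presses``,
    ``inactive_presses``, ``missing`` (0/1 session-failure flag).
``irritability``
    one row per bottle-brush assay — ``rat_id``, ``timepoint``
    (baseline/withdrawal), ``aggressive``, ``defensive``, ``total``.

Day indices count sessions, not calendar days (sessions ran 5 days/week);
phases are stored long-format. Excluded rats are dropped before any index
computation.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "PHASE_DURATION_H",
    "SEXES",
    "GROUPS",
    "TIMEPOINTS",
    "SchemaError",
    "ImputationWarning",
    "StudyTables",
    "read_study_tables",
    "write_study_tables",
    "validate_study_tables",
    "impute_missing_sessions",
]

PHASES = ("ShA", "LgA", "PreShock", "Shock", "PR")
SEXES = ("F", "M")
GROUPS = ("cocaine", "naive")
TIMEPOINTS = ("baseline", "withdrawal")

#: Fixed session durations in hours for phases whose length is part of the design.
PHASE_DURATION_H = {"ShA": 2.0, "LgA": 6.0, "PreShock": 1.0, "Shock": 1.0}

#: Number of daily sessions per phase (PR is tested up to three times).
PHASE_MAX_DAYS = {"ShA": 10, "LgA": 14, "PreShock": 1, "Shock": 1, "PR": 3}

RAT_COLUMNS = ["rat_id", "sex", "cohort", "group", "excluded"]
SESSION_COLUMNS = [
    "rat_id",
    "phase",
    "day_index",
    "duration_h",
    "infusions",
    "hour1_infusions",
    "active_presses",
    "inactive_presses",
    "missing",
]
IRRITABILITY_COLUMNS = ["rat_id", "timepoint", "aggressive", "defensive", "total"]


class SchemaError(ValueError):
    """A study table violates the documented schema or a record invariant."""


class ImputationWarning(UserWarning):
    """A missing session could not be imputed by the two-neighbour rule."""


class StudyTables(NamedTuple):
    """The three validated study tables."""

    rats: pd.DataFrame
    sessions: pd.DataFrame
    irritability: pd.DataFrame


def _fail(table: str, rows: Iterable[int], message: str) -> None:
    rows = sorted(int(r) for r in rows)
    raise SchemaError(f"{table}: {message} (rows {rows})")


def _check(table: str, frame: pd.DataFrame, bad: pd.Series, message: str) -> None:
    if bool(bad.any()):
        _fail(table, frame.index[bad], message)


def validate_rats(rats: pd.DataFrame) -> pd.DataFrame:
    missing_cols = set(RAT_COLUMNS) - set(rats.columns)
    if missing_cols:
        raise SchemaError(f"rats: missing columns {sorted(missing_cols)}")
    rats = rats[RAT_COLUMNS].copy()
    _check("rats", rats, rats["rat_id"].isna() | (rats["rat_id"].astype(str) == ""),
           "rat_id missing")
    rats["rat_id"] = rats["rat_id"].astype(str)
    _check("rats", rats, rats["rat_id"].duplicated(keep=False), "duplicate rat_id")
    _check("rats", rats, ~rats["sex"].isin(SEXES), "sex must be F or M")
    _check("rats", rats, rats["cohort"].isna(), "cohort missing")
    rats["cohort"] = rats["cohort"].astype(int)
    _check("rats", rats, rats["cohort"] < 1, "cohort must be >= 1")
    _check("rats", rats, ~rats["group"].isin(GROUPS), "group must be cocaine or naive")
    rats["excluded"] = rats["excluded"].astype(int).astype(bool)
    return rats


def validate_sessions(sessions: pd.DataFrame, rats: pd.DataFrame | None = None) -> pd.DataFrame:
    missing_cols = set(SESSION_COLUMNS) - set(sessions.columns)
    if missing_cols:
        raise SchemaError(f"sessions: missing columns {sorted(missing_cols)}")
    s = sessions[SESSION_COLUMNS].copy()
    s["rat_id"] = s["rat_id"].astype(str)
    _check("sessions", s, ~s["phase"].isin(PHASES), "unknown phase label")
    for col in ("day_index", "infusions", "hour1_infusions", "active_presses",
                "inactive_presses", "missing"):
        _check("sessions", s, s[col].isna(), f"{col} missing")
        s[col] = s[col].astype(int)
    s["duration_h"] = s["duration_h"].astype(float)
    s["missing"] = s["missing"].astype(bool)

    _check("sessions", s, s.duplicated(["rat_id", "phase", "day_index"], keep=False),
           "duplicate (rat_id, phase, day_index)")
    max_days = s["phase"].map(PHASE_MAX_DAYS)
    _check("sessions", s, (s["day_index"] < 1) | (s["day_index"] > max_days),
           "day_index out of range for phase")
    fixed = s["phase"].map(PHASE_DURATION_H)
    _check("sessions", s, fixed.notna() & (s["duration_h"] != fixed),
           "duration_h inconsistent with phase")
    for col in ("infusions", "hour1_infusions", "active_presses", "inactive_presses"):
        _check("sessions", s, s[col] < 0, f"{col} must be >= 0")
    ok = s["missing"]  # failed sessions carry placeholder zeros
    _check("sessions", s, ~ok & (s["hour1_infusions"] > s["infusions"]),
           "hour1_infusions exceeds infusions")
    _check("sessions", s, ~ok & (s["infusions"] > s["active_presses"]),
           "infusions exceed active lever presses (FR1)")

    if rats is not None:
        known = set(rats["rat_id"])
        _check("sessions", s, ~s["rat_id"].isin(known), "rat_id not in rats table")
        naive = set(rats.loc[rats["group"] == "naive", "rat_id"])
        _check("sessions", s, s["rat_id"].isin(naive),
               "naive rats must have no self-administration sessions")
    return s


def validate_irritability(irritability: pd.DataFrame,
                          rats: pd.DataFrame | None = None) -> pd.DataFrame:
    missing_cols = set(IRRITABILITY_COLUMNS) - set(irritability.columns)
    if missing_cols:
        raise SchemaError(f"irritability: missing columns {sorted(missing_cols)}")
    irr = irritability[IRRITABILITY_COLUMNS].copy()
    irr["rat_id"] = irr["rat_id"].astype(str)
    _check("irritability", irr, ~irr["timepoint"].isin(TIMEPOINTS),
           "timepoint must be baseline or withdrawal")
    for col in ("aggressive", "defensive", "total"):
        irr[col] = irr[col].astype(float)
        _check("irritability", irr, irr[col].isna() | (irr[col] < 0),
               f"{col} must be a number >= 0")
    _check("irritability", irr,
           (irr["total"] - irr["aggressive"] - irr["defensive"]).abs() > 1e-9,
           "total must equal aggressive + defensive")
    _check("irritability", irr,
           irr.duplicated(["rat_id", "timepoint"], keep=False),
           "duplicate (rat_id, timepoint)")
    if rats is not None:
        known = set(rats["rat_id"])
        _check("irritability", irr, ~irr["rat_id"].isin(known),
               "rat_id not in rats table")
    return irr


def validate_study_tables(rats: pd.DataFrame, sessions: pd.DataFrame,
                          irritability: pd.DataFrame) -> StudyTables:
    """Validate the three tables jointly and return canonicalised copies."""
    rats = validate_rats(rats)
    sessions = validate_sessions(sessions, rats)
    irritability = validate_irritability(irritability, rats)
    return StudyTables(rats, sessions, irritability)


def read_study_tables(rats_path: str | Path, sessions_path: str | Path,
                      irritability_path: str | Path) -> StudyTables:
    """Read and validate the three study CSVs.

    Empty files (header only) yield empty, correctly typed tables. Any
    invariant violation raises :class:`SchemaError` naming the offending rows
    (0-based data-row positions).
    """
    rats = pd.read_csv(rats_path)
    sessions = pd.read_csv(sessions_path)
    irritability = pd.read_csv(irritability_path)
    if rats.empty:
        rats = pd.DataFrame(columns=RAT_COLUMNS)
    if sessions.empty:
        sessions = pd.DataFrame(columns=SESSION_COLUMNS)
    if irritability.empty:
        irritability = pd.DataFrame(columns=IRRITABILITY_COLUMNS)
    return validate_study_tables(rats, sessions, irritability)


def write_study_tables(tables: StudyTables, out_dir: str | Path) -> dict[str, Path]:
    """Write rats/sessions/irritability CSVs to *out_dir*; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    frames = {"rats": tables.rats.copy(), "sessions": tables.sessions.copy(),
              "irritability": tables.irritability.copy()}
    for col, frame in (("excluded", frames["rats"]), ("missing", frames["sessions"])):
        frame[col] = frame[col].astype(int)
    for name, frame in frames.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def impute_missing_sessions(
    values: Sequence[float],
    missing: Sequence[bool] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Impute isolated interior gaps in a daily intake series.

    A session lost to equipment failure is replaced by the arithmetic mean of
    the adjacent days' values. Only isolated interior gaps are defined by that
    rule: runs of two or more consecutive missing days, and missing first or
    last days, are left unresolved (NaN) with an :class:`ImputationWarning`.

    Parameters
    ----------
    values
        Per-day values ordered by consecutive ``day_index``; gaps may be NaN.
    missing
        Optional explicit gap mask; defaults to ``isnan(values)``.

    Returns
    -------
    completed : ndarray of float
        The series with imputable gaps filled; unresolved gaps stay NaN.
    imputed : ndarray of bool
        True where a value was filled in.
    unresolved : ndarray of bool
        True where a gap could not be imputed.
    """
    vals = np.asarray(values, dtype=float).copy()
    if missing is None:
        gap = np.isnan(vals)
    else:
        gap = np.asarray(missing, dtype=bool).copy()
        if gap.shape != vals.shape:
            raise ValueError("missing mask length must match values length")
        vals[gap] = np.nan
    n = vals.size
    imputed = np.zeros(n, dtype=bool)
    unresolved = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(gap):
        interior = 0 < i < n - 1
        if interior and not gap[i - 1] and not gap[i + 1]:
            vals[i] = 0.5 * (vals[i - 1] + vals[i + 1])
            imputed[i] = True
        else:
            unresolved[i] = True
    if unresolved.any():
        warnings.warn(
            f"{int(unresolved.sum())} missing day(s) at positions "
            f"{np.flatnonzero(unresolved).tolist()} could not be imputed "
            "(consecutive or terminal gap); left unresolved",
            ImputationWarning,
            stacklevel=2,
        )
    return vals, imputed, unresolved
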