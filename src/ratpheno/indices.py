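"""Cohort×sex z-score indices, the Addiction Index, and phenotype labels.

Each behavioral metric is normalised within its (cohort, sex) group,
``z = (x − μ)/σ`` with the group's sample mean and SD (n−1 denominator),
which removes cohort batch effects and sex main effects before scoring.
Four indices result (escalation, motivation, compulsivity, irritability).
The **Addiction Index** is the unweighted mean of the escalation, motivation
and compulsivity indices — irritability is excluded because it is
uncorrelated with the other three. Animals are labelled:

* ``resilient`` / ``vulnerable`` — mean intake over the last three LgA
  sessions below 50 infusions (≈ 8/h over 6 h, short-access levels) vs at or
  above it;
* ``Low`` / ``Mild`` / ``Moderate`` / ``Severe`` — ascending quartiles of the
  Addiction Index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data_model import StudyTables

__all__ = [
    "GroupZScorer",
    "group_zscore",
    "build_indices",
    "addiction_index",
    "classify_vulnerability",
    "severity_groups",
    "RESILIENT_THRESHOLD",
    "SEVERITY_LABELS",
    "INDEX_COLUMNS",
]

#: Mean last-3-day LgA intake below which a rat is resilient (strict <).
RESILIENT_THRESHOLD = 50.0

SEVERITY_LABELS = ("Low", "Mild", "Moderate", "Severe")

INDEX_COLUMNS = [
    "rat_id",
    "escalation_z",
    "motivation_z",
    "compulsivity_z",
    "irritability_z",
    "addiction_index",
    "vulnerability",
    "severity",
]

#: Behavioral metric feeding each index.
INDEX_METRICS = {
    "escalation_z": "esc_mean_last3",
    "motivation_z": "pr_rewards_post_lga",
    "compulsivity_z": "shock_infusions",
    "irritability_z": "irritability_delta_total",
}


class GroupZScorer(BaseEstimator, TransformerMixin):
    """Standardise columns within groups defined by key columns.

    A scikit-learn transformer: :meth:`fit` learns per-group sample means and
    SDs (n−1 denominator) for each value column, ignoring NaN; :meth:`transform`
    maps raw values to z-scores using the learned statistics. Missing inputs
    stay missing. Groups with fewer than two non-missing values, or zero SD,
    are rejected at fit time.

    Parameters
    ----------
    columns : list of str
        Value columns to standardise.
    by : list of str, default ("cohort", "sex")
        Grouping key columns.

    Attributes
    ----------
    group_stats_ : DataFrame
        MultiIndex (group keys) × MultiIndex (column, {mu, sigma, n}) table.
    """

    def __init__(self, columns=None, by=("cohort", "sex")):
        self.columns = columns
        self.by = by

    def _resolve_columns(self, X: pd.DataFrame) -> list[str]:
        if self.columns is not None:
            return list(self.columns)
        return [c for c in X.columns if c not in self.by
                and pd.api.types.is_numeric_dtype(X[c])]

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("GroupZScorer requires a pandas DataFrame")
        by = list(self.by)
        cols = self._resolve_columns(X)
        for key in by:
            if key not in X.columns:
                raise ValueError(f"grouping column {key!r} not in input")
        stats = {}
        for col in cols:
            grouped = X.groupby(by, observed=True)[col]
            mu = grouped.mean()
            sigma = grouped.std(ddof=1)
            n = grouped.count()
            bad = (n < 2) | sigma.isna() | (sigma == 0)
            if bad.any():
                offenders = list(n.index[bad])
                raise ValueError(
                    f"column {col!r}: groups {offenders} have <2 values or zero "
                    "standard deviation; z-scores are undefined there"
                )
            stats[col] = pd.DataFrame({"mu": mu, "sigma": sigma, "n": n})
        self.columns_ = cols
        self.group_stats_ = pd.concat(stats, axis=1)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "group_stats_")
        by = list(self.by)
        keys = pd.MultiIndex.from_frame(X[by]) if len(by) > 1 else X[by[0]]
        out = {}
        for col in self.columns_:
            mu = self.group_stats_[(col, "mu")].reindex(keys).to_numpy()
            sigma = self.group_stats_[(col, "sigma")].reindex(keys).to_numpy()
            out[col] = (X[col].to_numpy(float) - mu) / sigma
        return pd.DataFrame(out, index=X.index)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "group_stats_")
        return np.asarray(self.columns_, dtype=object)


def group_zscore(values, keys) -> tuple[np.ndarray, pd.DataFrame]:
    """Z-score *values* within groups given by *keys*.

    Thin functional wrapper over :class:`GroupZScorer`. *keys* is a sequence
    of per-observation group labels (tuples for compound keys). Returns the
    z-scores and the learned per-group (mu, sigma, n) table.
    """
    values = np.asarray(values, dtype=float)
    frame = pd.DataFrame({"value": values, "group": list(keys)})
    scorer = GroupZScorer(columns=["value"], by=("group",)).fit(frame)
    z = scorer.transform(frame)["value"].to_numpy()
    return z, scorer.group_stats_["value"]


def addiction_index(escalation_z, motivation_z, compulsivity_z):
    """Unweighted mean of the three addiction indices; NaN unless all present."""
    cols = np.column_stack([
        np.asarray(escalation_z, dtype=float).ravel(),
        np.asarray(motivation_z, dtype=float).ravel(),
        np.asarray(compulsivity_z, dtype=float).ravel(),
    ])
    ai = cols.mean(axis=1)  # NaN propagates: complete cases only
    return ai if ai.size > 1 else float(ai[0])


def classify_vulnerability(esc_mean_last3):
    """Label rats resilient (< 50 mean infusions/LgA session) or vulnerable.

    Accepts a scalar or array; NaN inputs yield missing labels. The boundary
    value 50 is vulnerable (resilience is defined by a strict inequality).
    """
    x = np.asarray(esc_mean_last3, dtype=float)
    if (x < 0).any():
        raise ValueError("mean intake must be >= 0")
    labels = np.where(x < RESILIENT_THRESHOLD, "resilient", "vulnerable").astype(object)
    labels[np.isnan(x)] = None
    return labels if x.ndim else labels.item()


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def severity_groups(ai_values) -> np.ndarray:
    """Quartile severity labels (Low/Mild/Moderate/Severe) from the Addiction Index.

    Rats with a non-missing AI are ranked ascending (ties broken by stable
    input order) and split at cumulative counts ``round_half_up(N·k/4)`` for
    k = 1..3. Missing AI leaves the label unassigned (None).
    """
    ai = np.asarray(ai_values, dtype=float)
    present = ~np.isnan(ai)
    n = int(present.sum())
    if n < 4:
        raise ValueError(f"need >= 4 rats with an Addiction Index, got {n}")
    order = np.argsort(ai[present], kind="stable")
    cuts = [_round_half_up(n * k / 4) for k in (1, 2, 3)]
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    codes = np.searchsorted(cuts, ranks, side="left")
    labels = np.full(ai.shape, None, dtype=object)
    labels[present] = np.asarray(SEVERITY_LABELS, dtype=object)[codes]
    return labels


def build_indices(summaries: pd.DataFrame, rats: pd.DataFrame,
                  assign_severity: bool = True) -> pd.DataFrame:
    """Build the per-rat index table from behavioral summaries.

    Joins summaries to rat metadata, z-scores each metric per (cohort, sex),
    averages the three addiction indices into the Addiction Index (complete
    cases only) and attaches vulnerability and severity labels.
    """
    rats = rats[(rats["group"] == "cocaine") & (~rats["excluded"])]
    merged = summaries.merge(rats[["rat_id", "cohort", "sex"]], on="rat_id",
                             how="inner", validate="one_to_one")

    metrics = list(INDEX_METRICS.values())
    scorer = GroupZScorer(columns=metrics, by=("cohort", "sex")).fit(merged)
    z = scorer.transform(merged)

    table = pd.DataFrame({"rat_id": merged["rat_id"]})
    for index_col, metric in INDEX_METRICS.items():
        table[index_col] = z[metric].to_numpy()
    table["addiction_index"] = addiction_index(
        table["escalation_z"], table["motivation_z"], table["compulsivity_z"]
    )
    table["vulnerability"] = classify_vulnerability(merged["esc_mean_last3"])
    if assign_severity:
        table["severity"] = severity_groups(table["addiction_index"])
    else:
        table["severity"] = None
    return table[INDEX_COLUMNS]
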