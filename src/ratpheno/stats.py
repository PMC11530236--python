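"""Effect sizes, correlations, t-tests, battery PCA, and power analysis.

The battery behind the headline claims: pooled-SD Cohen's d with 95%
confidence intervals, Pearson correlation, Student's t statistics, PCA of
the standardized index matrix, and the per-group sample size needed to
detect a standardized effect with a two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "StatResult",
    "PCAResult",
    "cohens_d",
    "pearson_r",
    "two_group_t",
    "IndexPCA",
    "pca_indices",
    "power_two_sample_t",
    "n_per_group_for_power",
]


@dataclass(frozen=True)
class StatResult:
    """One test's outcome: estimate, 95% CI, group sizes, two-sided p."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


@dataclass(frozen=True)
class PCAResult:
    """Loadings (variables × components) and explained-variance fractions."""

    loadings: pd.DataFrame
    explained_fraction: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.explained_fraction)


def _clean_pair(x, y=None, paired=False):
    x = np.asarray(x, dtype=float)
    if y is None:
        return x
    y = np.asarray(y, dtype=float)
    if paired and x.size != y.size:
        raise ValueError("paired samples must have equal length")
    return x, y


def cohens_d(x, y, name: str = "cohens_d", ci_method: str = "asymptotic") -> StatResult:
    """Pooled-SD standardized mean difference with a 95% CI.

    d = (mean(x) − mean(y)) / s_pooled with the (n−1)-weighted pooled SD.
    The default CI is the asymptotic normal interval
    d ± 1.96·√((n1+n2)/(n1·n2) + d²/(2(n1+n2−2))); ``ci_method="noncentral"``
    inverts the noncentral-t distribution of the t statistic instead. The
    p-value is from the pooled two-sample t-test.
    """
    x, y = _clean_pair(x, y)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 observations")
    df = n1 + n2 - 2
    s_pooled = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df)
    if s_pooled == 0:
        raise ValueError("pooled standard deviation is zero; d undefined")
    d = (x.mean() - y.mean()) / s_pooled
    scale = np.sqrt(n1 * n2 / (n1 + n2))
    t_stat = d * scale
    p = 2.0 * sps.t.sf(abs(t_stat), df)
    if ci_method == "asymptotic":
        se = np.sqrt((n1 + n2) / (n1 * n2) + d * d / (2 * df))
        lo, hi = d - 1.96 * se, d + 1.96 * se
    elif ci_method == "noncentral":
        # invert: find noncentrality bounds whose t quantiles bracket t_stat
        lo = _nc_root(t_stat, df, upper=False) / scale
        hi = _nc_root(t_stat, df, upper=True) / scale
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return StatResult(name, float(d), float(lo), float(hi), n1, n2, float(p))


def _nc_root(t_stat: float, df: int, upper: bool, level: float = 0.95) -> float:
    """Noncentrality parameter whose noncentral-t places t_stat at a CI edge."""
    from scipy.optimize import brentq

    target = (1 - level) / 2 if upper else 1 - (1 - level) / 2
    span = abs(t_stat) + 10.0

    def f(nc):
        return sps.nct.cdf(t_stat, df, nc) - target

    try:
        return brentq(f, t_stat - span, t_stat + span, xtol=1e-8)
    except ValueError:  # root outside bracket at extreme effect sizes
        return t_stat + span if upper else t_stat - span


def pearson_r(x, y, name: str = "pearson_r") -> StatResult:
    """Pearson correlation with Fisher-z 95% CI and two-sided p."""
    x, y = _clean_pair(x, y, paired=True)
    n = x.size
    if n < 3:
        raise ValueError("Pearson r needs at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson r undefined for constant input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) < 1.0 and n > 3:
        z = np.arctanh(r)
        half = 1.96 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    elif abs(r) < 1.0:
        lo, hi = -1.0, 1.0  # Fisher interval is vacuous at n = 3
    else:
        lo = hi = r
    return StatResult(name, r, float(lo), float(hi), n, n, float(res.pvalue))


def two_group_t(x, y, paired: bool = False, name: str = "t_test") -> StatResult:
    """Student's t-test (pooled-variance unpaired, or paired).

    The estimate is the t statistic; the CI is on the (mean) difference.
    """
    x, y = _clean_pair(x, y, paired=paired)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 observations")
    if paired:
        diff = x - y
        if diff.std(ddof=1) == 0:
            raise ValueError("paired differences have zero variance")
        res = sps.ttest_rel(x, y)
        df = n1 - 1
        se = diff.std(ddof=1) / np.sqrt(n1)
        center = diff.mean()
    else:
        sx2, sy2 = x.var(ddof=1), y.var(ddof=1)
        if sx2 == 0 and sy2 == 0:
            raise ValueError("both samples are constant; t undefined")
        res = sps.ttest_ind(x, y, equal_var=True)
        df = n1 + n2 - 2
        sp = np.sqrt(((n1 - 1) * sx2 + (n2 - 1) * sy2) / df)
        se = sp * np.sqrt(1 / n1 + 1 / n2)
        center = x.mean() - y.mean()
    tcrit = sps.t.ppf(0.975, df)
    t_stat = float(res.statistic)
    # express the CI on the t scale so it brackets the reported statistic
    lo = (center - tcrit * se) / se if se > 0 else t_stat
    hi = (center + tcrit * se) / se if se > 0 else t_stat
    return StatResult(name, t_stat, float(lo), float(hi), n1, n2,
                      float(res.pvalue))


class IndexPCA(BaseEstimator, TransformerMixin):
    """PCA of a behavioral battery with centering and unit scaling.

    Columns are centered and scaled to unit sample SD, and the correlation
    matrix is eigendecomposed. Loadings are unit eigenvectors with the sign
    fixed so each component's largest-magnitude loading is positive, making
    results reproducible across linear-algebra backends.

    Attributes (after fit)
    ----------------------
    loadings_ : DataFrame, variables × PC1..PCk
    explained_variance_ratio_ : ndarray, descending, sums to 1
    eigenvalues_ : ndarray
    mean_, scale_ : per-column centering/scaling constants
    """

    def fit(self, X, y=None):
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        values = frame.to_numpy(dtype=float)
        if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
            raise ValueError("need a 2-D matrix with >= 2 rows and >= 2 columns")
        if np.isnan(values).any():
            raise ValueError("matrix must be complete cases (no NaN)")
        scale = values.std(axis=0, ddof=1)
        if (scale == 0).any():
            bad = [str(frame.columns[i]) for i in np.flatnonzero(scale == 0)]
            raise ValueError(f"constant columns have no correlation structure: {bad}")
        self.mean_ = values.mean(axis=0)
        self.scale_ = scale
        corr = np.corrcoef(values, rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        eigval = np.clip(eigval, 0.0, None)
        for j in range(eigvec.shape[1]):
            if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
                eigvec[:, j] = -eigvec[:, j]
        self.eigenvalues_ = eigval
        self.explained_variance_ratio_ = eigval / eigval.sum()
        self.loadings_ = pd.DataFrame(
            eigvec, index=frame.columns,
            columns=[f"PC{j + 1}" for j in range(eigvec.shape[1])])
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        values = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return values @ self.loadings_.to_numpy()

    def result(self) -> PCAResult:
        check_is_fitted(self, "loadings_")
        return PCAResult(self.loadings_.copy(),
                         self.explained_variance_ratio_.copy(),
                         self.eigenvalues_.copy())


def pca_indices(matrix) -> PCAResult:
    """PCA of a complete-case rats × variables index matrix (see IndexPCA)."""
    return IndexPCA().fit(matrix).result()


def power_two_sample_t(n_per_group: int, d: float, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test under a noncentral-t alternative."""
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    nc = d * np.sqrt(n_per_group / 2.0)
    crit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc))


def n_per_group_for_power(d: float, alpha: float = 0.05,
                          power: float = 0.80) -> int:
    """Smallest per-group n giving the target power for effect size d.

    Two-sided pooled two-sample t-test; power computed exactly from the
    noncentral t distribution, incrementing n from 2.
    """
    if d <= 0:
        raise ValueError("effect size d must be > 0")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    n = 2
    while power_two_sample_t(n, d, alpha) < power:
        n += 1
        if n > 10_000_000:  # pragma: no cover
            raise RuntimeError("sample size search did not converge")
    return n
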