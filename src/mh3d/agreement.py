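"""Observer-agreement and association statistics for hole measurements.

Automated 3D morphometry is judged against human calliper measurements
with the classical agreement toolkit: Bland-Altman limits of agreement
with t-based confidence intervals, Spearman rank correlation screens,
Shapiro-Wilk normality checks, a quadratic-versus-linear nested model
comparison (do base and minimum diameters scale nonlinearly?), and a
cross-tabulation of size classes with a Stuart-Maxwell marginal
homogeneity test (does reclassification shift the class distribution?).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "bland_altman",
    "spearman_assoc",
    "normality_test",
    "quad_vs_linear",
    "size_crosstab",
    "stuart_maxwell",
    "IVTS_CLASSES",
]

IVTS_CLASSES = ("small", "medium", "large")


@dataclass
class PairedMeasurements:
    """Two aligned measurement series on the same eyes (um)."""

    ids: list
    a: np.ndarray
    b: np.ndarray
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, float)
        self.b = np.asarray(self.b, float)
        if not (len(self.ids) == len(self.a) == len(self.b)):
            raise ValueError("ids, a and b must have equal lengths")
        if len(self.a) < 3:
            raise ValueError("need at least 3 paired measurements")

    @classmethod
    def from_frames(cls, df_a: pd.DataFrame, df_b: pd.DataFrame,
                    label_a: str = "a", label_b: str = "b"
                    ) -> "PairedMeasurements":
        """Align two (id, value) tables on their shared ids."""
        m = df_a.merge(df_b, on="id", suffixes=("_a", "_b"))
        return cls(m["id"].tolist(), m["value_a"].to_numpy(),
                   m["value_b"].to_numpy(), label_a, label_b)


@dataclass
class AgreementResult:
    """Bland-Altman agreement summary (differences defined as a - b)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_mean: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    n: int
    k: float

    def as_dict(self) -> dict:
        return asdict(self)


def bland_altman(pairs: PairedMeasurements, k: float = 1.96
                 ) -> AgreementResult:
    """Bland-Altman limits of agreement with confidence intervals.

    With d = a - b: the bias is mean(d), the limits of agreement are
    mean(d) +/- k sd(d) (k = 1.96 for 95% limits).  The CI of the bias
    uses the t quantile (n-1 df) with standard error sd/sqrt(n); each
    limit's CI uses the classical variance approximation, standard error
    sd * sqrt(3/n).

    A zero-variance difference series yields degenerate (zero-width)
    intervals with a warning.
    """
    d = pairs.a - pairs.b
    n = len(d)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        warnings.warn("zero-variance differences: limits of agreement and "
                      "their CIs are degenerate", stacklevel=2)
    t = float(stats.t.ppf(0.975, n - 1))
    se_mean = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(3.0 / n)
    lo = mean - k * sd
    hi = mean + k * sd
    return AgreementResult(
        mean_diff=mean, sd_diff=sd, loa_low=lo, loa_high=hi,
        ci_mean=(mean - t * se_mean, mean + t * se_mean),
        ci_loa_low=(lo - t * se_loa, lo + t * se_loa),
        ci_loa_high=(hi - t * se_loa, hi + t * se_loa),
        n=n, k=k)


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties) with two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length series of n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant series: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def normality_test(x) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p value."""
    x = np.asarray(x, float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant series: normality test undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)


@dataclass
class QuadLinearComparison:
    """Nested-model comparison of y ~ x against y ~ x + x^2."""

    linear_params: np.ndarray
    quadratic_params: np.ndarray
    rss_linear: float
    rss_quadratic: float
    f_stat: float
    p_quadratic: float
    n: int

    def as_dict(self) -> dict:
        d = asdict(self)
        d["linear_params"] = list(self.linear_params)
        d["quadratic_params"] = list(self.quadratic_params)
        return d


def quad_vs_linear(x, y) -> QuadLinearComparison:
    """Fit y ~ x and y ~ x + x^2; test the quadratic improvement.

    The p value is the nested-model F test with (1, n-3) df, identical to
    the two-sided t test on the x^2 coefficient.  Raises on a degenerate
    design (constant x, or x taking fewer than 3 distinct values).
    """
    import statsmodels.api as sm

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length series of n >= 4")
    if len(np.unique(x)) < 3:
        raise ValueError("degenerate design: x must take >= 3 distinct values")
    X1 = sm.add_constant(x)
    X2 = sm.add_constant(np.column_stack([x, x * x]))
    fit1 = sm.OLS(y, X1).fit()
    fit2 = sm.OLS(y, X2).fit()
    rss1 = float(fit1.ssr)
    rss2 = float(fit2.ssr)
    n = len(x)
    df2 = n - 3
    if rss2 <= 0:
        f = math.inf
        p = 0.0
    else:
        f = (rss1 - rss2) / (rss2 / df2)
        p = float(stats.f.sf(f, 1, df2))
    return QuadLinearComparison(
        linear_params=np.asarray(fit1.params),
        quadratic_params=np.asarray(fit2.params),
        rss_linear=rss1, rss_quadratic=rss2,
        f_stat=float(f), p_quadratic=p, n=n)


def stuart_maxwell(table: np.ndarray) -> tuple[float, float]:
    """Stuart-Maxwell test of marginal homogeneity on a square table.

    With n_ij the count classified i by rater A and j by rater B, tests
    whether the two marginal distributions coincide.  d holds the first
    k-1 margin differences and S their covariance:
    S_ii = row_i + col_i - 2 n_ii, S_ij = -(n_ij + n_ji); the statistic
    d' S^- d is chi-squared with k-1 df.  A table with no off-diagonal
    entries is perfectly concordant: (0, 1) by convention.
    """
    t = np.asarray(table, float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("table must be square")
    k = t.shape[0]
    if np.allclose(t, np.diag(np.diag(t))):
        return 0.0, 1.0
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    d = (rows - cols)[:-1]
    S = np.empty((k - 1, k - 1))
    for i in range(k - 1):
        for j in range(k - 1):
            if i == j:
                S[i, j] = rows[i] + cols[i] - 2.0 * t[i, i]
            else:
                S[i, j] = -(t[i, j] + t[j, i])
    chi2 = float(d @ np.linalg.pinv(S) @ d)
    p = float(stats.chi2.sf(chi2, k - 1))
    return chi2, p


@dataclass
class CrosstabResult:
    table: np.ndarray
    n_reclassified: int
    chi2: float
    p: float
    classes: tuple[str, ...]
    test: str = "stuart-maxwell"

    def as_dict(self) -> dict:
        return {"table": self.table.tolist(),
                "n_reclassified": self.n_reclassified,
                "chi2": self.chi2, "p": self.p,
                "classes": list(self.classes), "test": self.test}


def size_crosstab(class_a, class_b,
                  classes: tuple[str, ...] = IVTS_CLASSES) -> CrosstabResult:
    """Cross-tabulate two IVTS classifications of the same eyes.

    Returns the k x k table (rows = first series), the number of eyes
    whose class changed (off-diagonal count), and the Stuart-Maxwell
    marginal homogeneity test.
    """
    a = list(class_a)
    b = list(class_b)
    if len(a) != len(b):
        raise ValueError("classification series must be aligned "
                         f"(got {len(a)} vs {len(b)})")
    idx = {c: i for i, c in enumerate(classes)}
    table = np.zeros((len(classes), len(classes)), int)
    for ca, cb in zip(a, b):
        table[idx[ca], idx[cb]] += 1
    n_re = int(table.sum() - np.trace(table))
    chi2, p = stuart_maxwell(table)
    return CrosstabResult(table=table, n_reclassified=n_re, chi2=chi2, p=p,
                          classes=tuple(classes))
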