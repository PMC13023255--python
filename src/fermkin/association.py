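"""Prediction regressions, starred correlation matrices, factorial ANOVA.

Three reporting devices tie fermentation chemistry to digestibility:

* simple OLS prediction equations Y = a + bX (X a fermentative
  digestibility, Y an odorant concentration or enzyme activity), with
  R^2 and the regression F-test p;
* pairwise Pearson correlation matrices with significance stars at
  p < 0.05 (*) and p < 0.01 (**), unadjusted for multiplicity;
* a two-way fixed-effects ANOVA (digestion method x fermentation time,
  balanced) with an LSD post hoc rendered as a compact letter display
  within each time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "RegressionFit", "LinearPredictionEquation", "fit_prediction_equation",
    "CorrelationMatrix", "correlation_matrix",
    "AnovaResult", "factorial_anova", "lsd_letters",
]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    predictor: str = "X"
    response: str = "Y"

    def equation(self) -> str:
        sign = "+" if self.intercept >= 0 else "-"
        return (f"Y = {self.slope:.4f}X {sign} {abs(self.intercept):.4f}")


class LinearPredictionEquation(BaseEstimator, RegressorMixin):
    """Simple OLS line with F-test inference, sklearn estimator style.

    ``fit(X, y)`` accepts a 1-d predictor or single-column 2-d array.
    Fitted attributes: ``slope_``, ``intercept_``, ``r_squared_``,
    ``p_value_``, ``n_``.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have equal length")
        if x.size < 3:
            raise ValueError("need at least 3 observations")
        if np.ptp(x) == 0:
            raise ValueError("constant predictor: rank-deficient design")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        self.intercept_, self.slope_ = map(float, res.params)
        self.r_squared_ = float(res.rsquared)
        self.p_value_ = float(res.f_pvalue)
        self.n_ = int(x.size)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x


def fit_prediction_equation(x, y, predictor: str = "X",
                            response: str = "Y") -> RegressionFit:
    est = LinearPredictionEquation().fit(x, y)
    return RegressionFit(slope=est.slope_, intercept=est.intercept_,
                         r_squared=est.r_squared_, p_value=est.p_value_,
                         n=est.n_, predictor=predictor, response=response)


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    dropped: list


def _star(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson r, two-sided p and star levels over columns.

    Constant columns are flagged in ``dropped`` and omitted. The
    diagonal is r = 1 with blank stars (no test against itself).
    """
    numeric = table.select_dtypes(include=[np.number])
    dropped = [c for c in numeric.columns if np.ptp(numeric[c].dropna()) == 0]
    cols = [c for c in numeric.columns if c not in dropped]
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = numeric[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 complete observations for "
                                 f"({cols[i]}, {cols[j]})")
            res = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    stars = p_df.map(_star)
    np.fill_diagonal(stars.values, "")
    return CorrelationMatrix(r=r_df, p=p_df, stars=stars, dropped=dropped)


@dataclass
class AnovaResult:
    ss: dict
    df: dict
    f: dict
    p: dict
    ms_error: float
    sem: float
    n_cell: int
    cell_means: pd.DataFrame
    letters: dict
    degenerate: bool = False


def factorial_anova(data: pd.DataFrame, value: str,
                    method_col: str = "method", time_col: str = "time_h",
                    alpha: float = 0.05) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction on a balanced design.

    Decomposes SS into method, time, method x time and error (type I ==
    type II == type III under balance); SEM = sqrt(MS_error / n_cell);
    LSD compact letters are assigned to method means separately within
    each time point.
    """
    counts = data.groupby([method_col, time_col])[value].count()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: equal cell sizes required")
    n_cell = int(counts.iloc[0])
    if n_cell < 2:
        raise ValueError("need at least 2 replicates per cell")

    d = data.rename(columns={value: "y", method_col: "m", time_col: "t"})
    fit = smf.ols("y ~ C(m) * C(t)", data=d).fit()
    tab = anova_lm(fit, typ=1)
    keys = {"C(m)": "method", "C(t)": "time", "C(m):C(t)": "interaction",
            "Residual": "error"}
    ss = {keys[k]: float(tab.loc[k, "sum_sq"]) for k in keys}
    df = {keys[k]: float(tab.loc[k, "df"]) for k in keys}
    f = {keys[k]: float(tab.loc[k, "F"]) for k in keys if k != "Residual"}
    p = {keys[k]: float(tab.loc[k, "PR(>F)"]) for k in keys
         if k != "Residual"}
    ms_error = ss["error"] / df["error"] if df["error"] > 0 else 0.0
    sem = float(np.sqrt(ms_error / n_cell))
    cell_means = (d.groupby(["m", "t"])["y"].mean().rename(value)
                  .reset_index()
                  .rename(columns={"m": method_col, "t": time_col}))

    # zero within-cell variance everywhere: MS_error is 0 up to rounding
    degenerate = ms_error <= 1e-12 * max(sum(ss.values()), 1.0)
    letters: dict = {}
    if not degenerate:
        for t_val, grp in cell_means.groupby(time_col):
            means = dict(zip(grp[method_col], grp[value]))
            letters[t_val] = lsd_letters(means, ms_error, n_cell,
                                         df_error=int(df["error"]),
                                         alpha=alpha)
    return AnovaResult(ss=ss, df=df, f=f, p=p, ms_error=float(ms_error),
                       sem=sem, n_cell=n_cell, cell_means=cell_means,
                       letters=letters, degenerate=degenerate)


def lsd_letters(means: dict, ms_error: float, n_cell: int,
                df_error: int, alpha: float = 0.05) -> dict:
    """Compact letter display from pairwise LSD comparisons.

    Two means differ iff |m_i - m_j| > LSD with
    LSD = t(1 - alpha/2, df_error) * sqrt(2 * MS_error / n). Since
    significance here depends only on the absolute difference, the
    letter groups are maximal runs of the means sorted in descending
    order; letters start at "a" for the largest mean.
    """
    if len(means) < 2:
        raise ValueError("need at least 2 groups")
    if ms_error <= 0:
        raise ValueError("MS_error must be positive for LSD letters")
    lsd = stats.t.ppf(1.0 - alpha / 2.0, df_error) \
        * np.sqrt(2.0 * ms_error / n_cell)
    items = sorted(means.items(), key=lambda kv: -kv[1])
    names = [k for k, _ in items]
    vals = np.array([v for _, v in items])
    k = len(vals)
    # maximal intervals of mutually non-different (within-LSD) means
    groups = []
    start = 0
    while start < k:
        end = start
        while end + 1 < k and vals[start] - vals[end + 1] <= lsd:
            end += 1
        groups.append((start, end))
        start += 1
    # keep only maximal intervals
    maximal = [g for g in groups
               if not any(o != g and o[0] <= g[0] and g[1] <= o[1]
                          for o in groups)]
    maximal.sort()
    letters = {name: "" for name in names}
    for letter_idx, (lo, hi) in enumerate(maximal):
        ch = chr(ord("a") + letter_idx)
        for i in range(lo, hi + 1):
            letters[names[i]] += ch
    return letters
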