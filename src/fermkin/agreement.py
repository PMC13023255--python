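"""In vitro vs in vivo agreement statistics.

Pearson's r measures precision only; Lin's concordance correlation
coefficient (CCC) additionally penalises location and scale shifts:

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)

with population (n-denominator) moments, per Lin's original estimator.
|CCC| <= |r| always, with equality iff the two members share mean and
variance. Agreement is graded poor (CCC < 0.90), moderate
(0.90 <= CCC <= 0.95) or high (CCC > 0.95); the band boundaries are
inclusive to "moderate".

The default confidence interval applies Fisher's inverse-hyperbolic-
tangent transform to the CCC with Lin's asymptotic variance and
back-transforms a normal interval; a nonparametric bootstrap
alternative is available behind ``method="bootstrap"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AgreementResult", "pearson", "lin_ccc", "ccc_ci",
           "classify_ccc", "agreement_summary", "agreement_table"]


@dataclass(frozen=True)
class AgreementResult:
    r: float
    p_value: float
    ccc: float
    ci_low: float
    ci_high: float
    category: str
    n: int


def _paired(x, y):
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in paired series")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    return x, y


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided t-distribution p."""
    x, y = _paired(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x, y = _paired(x, y)
    sx2 = x.var()          # ddof=0: population denominators
    sy2 = y.var()
    if sx2 == 0 and sy2 == 0:
        raise ValueError("both members constant: CCC undefined")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2))


def ccc_ci(x, y, level: float = 0.95, method: str = "z",
           n_boot: int = 2000, seed: int | None = None,
           ) -> tuple[float, float]:
    """Confidence interval for Lin's CCC.

    ``method="z"`` (default): Fisher z-transform with Lin's asymptotic
    variance, normal quantiles, back-transformed with tanh.
    ``method="bootstrap"``: percentile bootstrap over pairs.
    |CCC| = 1 degenerates to a point interval.
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs for an interval")
    ccc = lin_ccc(x, y)
    if abs(ccc) >= 1.0 - 1e-15:
        return ccc, ccc

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        vals = np.array([lin_ccc(x[i], y[i]) for i in idx])
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(vals, [a, 1.0 - a])
        return float(lo), float(hi)
    if method != "z":
        raise ValueError(f"unknown CI method {method!r}")

    r, _ = pearson(x, y)
    sx = x.std()
    sy = y.std()
    u = (x.mean() - y.mean()) / np.sqrt(sx * sy)
    z = np.arctanh(ccc)
    # Lin's asymptotic variance of the z-transformed estimate
    var_z = ((1 - r ** 2) * ccc ** 2 / ((1 - ccc ** 2) * r ** 2)
             + 2 * ccc ** 3 * (1 - ccc) * u ** 2 / (r * (1 - ccc ** 2) ** 2)
             - ccc ** 4 * u ** 4 / (2 * r ** 2 * (1 - ccc ** 2) ** 2)
             ) / (n - 2)
    q = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    half = q * np.sqrt(max(var_z, 0.0))
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def classify_ccc(ccc: float) -> str:
    """Grade agreement: poor < 0.90 <= moderate <= 0.95 < high."""
    if not np.isfinite(ccc):
        raise ValueError("CCC must be finite")
    if ccc < 0.90:
        return "poor"
    if ccc <= 0.95:
        return "moderate"
    return "high"


def agreement_summary(x, y, level: float = 0.95, **ci_kwargs) -> AgreementResult:
    """Full agreement summary for one paired series."""
    x, y = _paired(x, y)
    r, p = pearson(x, y)
    ccc = lin_ccc(x, y)
    lo, hi = ccc_ci(x, y, level=level, **ci_kwargs)
    return AgreementResult(r=r, p_value=p, ccc=ccc, ci_low=lo, ci_high=hi,
                           category=classify_ccc(ccc), n=x.size)


def agreement_table(pairs: pd.DataFrame, by: list[str],
                    x: str = "in_vivo", y: str = "in_vitro",
                    level: float = 0.95) -> pd.DataFrame:
    """Agreement statistics per group of an already-paired long table.

    ``pairs`` carries one row per matched sample with columns ``x`` and
    ``y``; one :class:`AgreementResult` row is computed per unique
    combination of the ``by`` columns.
    """
    rows = []
    for key, grp in pairs.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        res = agreement_summary(grp[x].to_numpy(), grp[y].to_numpy(), level=level)
        rows.append(dict(zip(by, key)) | {
            "n": res.n, "r": res.r, "p_value": res.p_value,
            "ccc": res.ccc, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "category": res.category})
    return pd.DataFrame(rows)
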