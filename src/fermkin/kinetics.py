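"""Cumulative gas-production kinetics.

Fermentation gas accumulates along a sigmoid

    G(t) = A / (1 + (C / t)^B)

with A the asymptotic gas volume (mL), B a unitless switching
characteristic (steepness / microbial adaptation), and C the half-time
(h): G(C) = A/2 exactly. Two derived quantities describe the rate
profile:

    T_max = C * ((B - 1) / (B + 1))^(1/B)        (defined only for B > 1)
    R_max = A C^B T_max^(-B-1) / (1 + C^B T_max^(-B))^2

The R_max expression above is the form conventionally printed alongside
this model; the analytic derivative dG/dt at T_max is exactly B times
it. Both variants are computed and carried, labelled ``as_printed`` and
``derivative_consistent``, and neither is silently "corrected" into the
other. For B <= 1 the rate has no interior maximum (it is largest as
t -> 0+), so T_max/R_max are reported as undefined (NaN) rather than 0.
R_max is a volume rate and is reported in mL/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "model_g", "t_max", "r_max", "RateMax",
    "GasProductionCurve", "KineticFit", "fit_gas_curve", "kinetics_table",
]

_B_STARTS = (0.5, 1.0, 1.5, 2.0, 3.0)


def _check_params(A: float, B: float, C: float) -> None:
    if not (A > 0 and B > 0 and C > 0):
        raise ValueError(f"kinetic parameters must be positive, "
                         f"got A={A}, B={B}, C={C}")


def model_g(t, A: float, B: float, C: float):
    """Cumulative gas volume at time(s) t (h), mL.

    Vectorised over t; returns 0 at t = 0 (the right limit of the
    model, since (C/t)^B diverges there).
    """
    _check_params(A, B, C)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    with np.errstate(divide="ignore"):
        out = np.where(t > 0, A / (1.0 + (C / np.where(t > 0, t, 1.0)) ** B),
                       0.0)
    return out if out.ndim else float(out)


def t_max(B: float, C: float) -> float:
    """Time of maximum gas-production rate, h; NaN when B <= 1."""
    if not (B > 0 and C > 0):
        raise ValueError("B and C must be positive")
    if B <= 1.0:
        return float("nan")
    return C * ((B - 1.0) / (B + 1.0)) ** (1.0 / B)


@dataclass(frozen=True)
class RateMax:
    """Maximum gas-production rate in its two published forms (mL/h)."""

    as_printed: float
    derivative_consistent: float


def r_max(A: float, B: float, C: float,
          tmax: float | None = None) -> RateMax:
    """Maximum rate of gas production at T_max.

    ``as_printed`` is the conventional closed form; the slope of G at
    T_max is exactly B times larger and is reported as
    ``derivative_consistent``. Both are NaN when T_max is undefined
    (B <= 1).
    """
    if A < 0:
        raise ValueError("A must be nonnegative")
    if not (B > 0 and C > 0):
        raise ValueError("B and C must be positive")
    if tmax is None:
        tmax = t_max(B, C)
    if not np.isfinite(tmax):
        return RateMax(float("nan"), float("nan"))
    if A == 0:
        return RateMax(0.0, 0.0)
    core = A * C ** B * tmax ** (-B - 1.0) / (1.0 + C ** B * tmax ** -B) ** 2
    return RateMax(as_printed=core, derivative_consistent=B * core)


@dataclass
class KineticFit:
    """Fitted kinetic parameters and derived quantities for one bottle."""

    A: float
    B: float
    C: float
    rss: float
    converged: bool
    n_points: int
    t_max: float = field(init=False)
    r_max_printed: float = field(init=False)
    r_max_derivative: float = field(init=False)

    def __post_init__(self) -> None:
        if self.converged:
            self.t_max = t_max(self.B, self.C)
            rm = r_max(self.A, self.B, self.C, self.t_max)
            self.r_max_printed = rm.as_printed
            self.r_max_derivative = rm.derivative_consistent
        else:
            self.t_max = self.r_max_printed = self.r_max_derivative = \
                float("nan")


class GasProductionCurve(BaseEstimator, RegressorMixin):
    """Least-squares fit of the sigmoid gas model to one cumulative curve.

    scikit-learn estimator: ``fit(t, g)`` with ``t`` the observation
    times in hours (1-d or a single-column 2-d array) and ``g`` the
    cumulative volumes in mL. Observations at t = 0 are excluded from
    the residual sum (the model is defined there only by its limit).

    The loss surface is multi-modal in (A, B, C), so fitting multi-
    starts over a fixed grid — B in {0.5, 1, 1.5, 2, 3}, C at the
    quartiles of the observation times, A at 1.1x the largest observed
    volume — and keeps the lowest residual sum of squares, breaking
    ties toward the smaller B. Bounds: A in (0, 10*max G],
    B in (0.05, 10], C in (min t / 10, 10*max t].

    Fitted attributes: ``A_``, ``B_``, ``C_``, ``rss_``, ``converged_``,
    ``n_points_``, ``t_max_``, ``r_max_printed_``, ``r_max_derivative_``.
    """

    def __init__(self, b_starts: tuple = _B_STARTS, xtol: float = 1e-12,
                 ftol: float = 1e-12, min_points: int = 5):
        self.b_starts = b_starts
        self.xtol = xtol
        self.ftol = ftol
        self.min_points = min_points

    def fit(self, t, g):
        t = np.asarray(t, dtype=float).reshape(-1)
        g = np.asarray(g, dtype=float).reshape(-1)
        if t.shape != g.shape:
            raise ValueError("t and g must have the same length")
        if np.any(g < 0):
            raise ValueError("negative cumulative volume")
        keep = t > 0
        t, g = t[keep], g[keep]
        if t.size < self.min_points:
            raise ValueError(f"need at least {self.min_points} observations "
                             f"at t > 0, got {t.size}")
        order = np.argsort(t)
        t, g = t[order], g[order]

        gmax = float(g.max())
        if gmax <= 0:
            # flat-zero curve: nothing fermented, no meaningful fit
            self._set_fit(np.nan, np.nan, np.nan, np.inf, False, t.size)
            return self
        lo = np.array([1e-9, 0.05 + 1e-9, t.min() / 10.0])
        hi = np.array([10.0 * gmax, 10.0, 10.0 * t.max()])

        def resid(p):
            A, B, C = p
            return A / (1.0 + (C / t) ** B) - g

        a0 = min(1.1 * gmax, hi[0])
        c_starts = np.quantile(t, [0.25, 0.5, 0.75])
        best = None
        for b0 in self.b_starts:
            for c0 in c_starts:
                x0 = np.clip([a0, b0, c0], lo + 1e-12, hi - 1e-12)
                try:
                    sol = least_squares(resid, x0, bounds=(lo, hi),
                                        xtol=self.xtol, ftol=self.ftol,
                                        gtol=1e-14, method="trf")
                except Exception:  # pragma: no cover - solver edge cases
                    continue
                rss = float(2.0 * sol.cost)
                cand = (rss, float(sol.x[1]), sol)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is None:
            self._set_fit(np.nan, np.nan, np.nan, np.inf, False, t.size)
            return self
        rss, _, sol = best
        A, B, C = (float(v) for v in sol.x)
        self._set_fit(A, B, C, rss, True, t.size)
        return self

    def _set_fit(self, A, B, C, rss, converged, n):
        self.A_, self.B_, self.C_ = A, B, C
        self.rss_, self.converged_, self.n_points_ = rss, converged, n
        if converged:
            self.t_max_ = t_max(B, C)
            rm = r_max(A, B, C, self.t_max_)
            self.r_max_printed_ = rm.as_printed
            self.r_max_derivative_ = rm.derivative_consistent
        else:
            self.t_max_ = self.r_max_printed_ = self.r_max_derivative_ = \
                float("nan")

    def predict(self, t):
        if not getattr(self, "converged_", False):
            raise RuntimeError("no converged fit")
        return model_g(np.asarray(t, dtype=float).reshape(-1),
                       self.A_, self.B_, self.C_)

    def to_result(self) -> KineticFit:
        return KineticFit(A=self.A_, B=self.B_, C=self.C_, rss=self.rss_,
                          converged=self.converged_, n_points=self.n_points_)


def fit_gas_curve(times, volumes, **options) -> KineticFit:
    """Functional wrapper over :class:`GasProductionCurve`.

    Never raises on a fit failure in batch use: an unfittable curve
    comes back with ``converged=False`` and NaN parameters.
    """
    est = GasProductionCurve(**options)
    try:
        est.fit(times, volumes)
    except ValueError:
        raise
    return est.to_result()


def kinetics_table(gas: pd.DataFrame) -> pd.DataFrame:
    """Per-bottle fits and a per-cell (diet x method) summary.

    ``gas`` columns: bottle, diet, method, time_h, cum_ml. Returns the
    per-bottle fit frame; ``.attrs['summary']`` holds mean and SEM of
    A, B, C, T_max and both R_max variants per diet x method plus the
    count of failed fits, and ``.attrs['failures']`` the failed bottles.
    """
    fits = []
    for (diet, method, bottle), grp in gas.groupby(
            ["diet", "method", "bottle"], sort=True):
        res = fit_gas_curve(grp["time_h"].to_numpy(),
                            grp["cum_ml"].to_numpy())
        fits.append({"diet": diet, "method": method, "bottle": bottle,
                     "A": res.A, "B": res.B, "C": res.C,
                     "t_max": res.t_max,
                     "r_max_printed": res.r_max_printed,
                     "r_max_derivative": res.r_max_derivative,
                     "rss": res.rss, "converged": res.converged,
                     "n_points": res.n_points})
    fits = pd.DataFrame(fits)
    ok = fits[fits["converged"]]
    cols = ["A", "B", "C", "t_max", "r_max_printed", "r_max_derivative"]

    def sem(x):
        x = x.dropna()
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    summary = ok.groupby(["diet", "method"])[cols].agg(["mean", sem])
    summary.columns = [f"{c}_{'sem' if f == 'sem' else f}"
                       for c, f in summary.columns]
    summary = summary.reset_index()
    fails = (fits.groupby(["diet", "method"])["converged"]
             .apply(lambda s: int((~s).sum())).rename("n_failed")
             .reset_index())
    summary = summary.merge(fails, on=["diet", "method"], how="left")
    fits.attrs["summary"] = summary
    fits.attrs["failures"] = fits[~fits["converged"]]
    return fits
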