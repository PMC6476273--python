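"""Four-parameter logistic (4PL) dose-response analytics.

The sigmoid fitted throughout is

    f(x) = (A - D) / (1 + (x / C)**B) + D

with A the minimum asymptote (basal response at zero dose for B > 0), D the
maximum asymptote, C the inflection point (EC50) and B the steepness (Hill
slope). On top of the fit, this module computes the derived curve
characteristics used to compare engineered sensor strains:

* sensitivity  — lowest concentration producing a 2-fold change over basal,
* operational range — log10 span between 5% and 95% of the activated
  response, which has the closed form (2/|B|) * log10(19),
* tightness    — reciprocal of basal activity,
* dynamic range — maximum output / basal activity,

plus small utilities: exponential growth rate from OD600 series, residual /
R-squared reports, and the population-level mixture operator that composes a
consortium response as the weighted sum of its member strains' curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .curves import ResponseCurve

__all__ = [
    "FourPL",
    "CurveMetrics",
    "GrowthSeries",
    "ResidualSet",
    "MixtureSpec",
    "UnfittableError",
    "fourpl_eval",
    "fit_fourpl",
    "curve_metrics",
    "growth_rate",
    "r_squared",
    "compose_mixture",
    "span_fold_change",
]


class UnfittableError(ValueError):
    """Raised when dose-response data carry no fittable signal."""


@dataclass(frozen=True)
class FourPL:
    """Parameters of the four-parameter logistic curve."""

    A: float  # minimum asymptote (response units)
    B: float  # steepness / Hill slope (dimensionless)
    C: float  # inflection point (M)
    D: float  # maximum asymptote (response units)

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError("inflection point C must be > 0")

    def __call__(self, x):
        return fourpl_eval(self, x)


@dataclass(frozen=True)
class CurveMetrics:
    """Derived dose-response characteristics of a fitted 4PL.

    ``sensitivity`` is NaN when a 2-fold change over basal lies outside the
    open response interval (A, D); ``tightness`` is inf when basal is 0.
    """

    logEC50: float  # log10 M
    hill_slope: float
    sensitivity: float  # M; NaN when undefined
    operational_range_orders: float  # log10 units
    tightness: float  # 1 / response units
    dynamic_range: float
    basal: float
    emax: float


@dataclass(frozen=True)
class GrowthSeries:
    """An OD600 time series sampled on strictly increasing times (hours)."""

    times: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if t.shape != od.shape or t.ndim != 1:
            raise ValueError("times and od600 must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od <= 0):
            raise ValueError("od600 must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od600", od)


@dataclass(frozen=True)
class ResidualSet:
    """Observed vs predicted values with residuals e_i = y_i - f_i and R^2."""

    observed: np.ndarray
    predicted: np.ndarray
    residuals: np.ndarray
    r_squared: float


@dataclass(frozen=True)
class MixtureSpec:
    """A consortium: member curves (or 4PLs) and their population weights."""

    members: Sequence
    weights: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("mixture needs at least one member")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.members),):
            raise ValueError("one weight per member required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if not math.isclose(float(w.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 1 (got {w.sum()})")
        object.__setattr__(self, "weights", w)


def fourpl_eval(p: FourPL, x):
    """Evaluate the 4PL at dose(s) ``x`` (M). Defined at x = 0.

    For B > 0, x = 0 returns A; for B < 0 it returns D (the curve is then
    decreasing in its own parameterisation).
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0):
        raise ValueError("doses must be non-negative")
    out = np.empty(x.shape, dtype=float)
    zero = x == 0
    out[zero] = p.A if p.B > 0 else p.D
    xr = x[~zero] / p.C
    out[~zero] = (p.A - p.D) / (1.0 + xr**p.B) + p.D
    return float(out[0]) if scalar else out


def _initial_guess(doses: np.ndarray, responses: np.ndarray) -> tuple[float, ...]:
    """Data-quartile starting values for the 4PL fit."""
    order = np.argsort(doses)
    d, r = doses[order], responses[order]
    a0 = float(np.mean(r[d == d[0]]))
    d0 = float(np.mean(r[d == d[-1]]))
    pos = d[d > 0]
    mid = 0.5 * (a0 + d0)
    # dose whose response is nearest the midpoint, clipped into the grid
    idx = int(np.argmin(np.abs(r - mid)))
    c0 = d[idx] if d[idx] > 0 else float(np.median(pos))
    return a0, 1.0, math.log10(c0), d0


def fit_fourpl(
    curve: ResponseCurve | tuple[np.ndarray, np.ndarray],
    robust: bool = False,
    allow_decreasing: bool = False,
    rel_noise_floor: float = 1e-8,
) -> tuple[FourPL, ResidualSet]:
    """Least-squares 4PL fit in log10-dose space.

    Accepts a :class:`ResponseCurve` or a raw ``(doses, responses)`` pair
    (which may contain replicate points at the same dose). Zero doses enter
    through the A-limit of the model. ``robust=True`` switches to a soft-L1
    loss. Fits are constrained to activating curves (B > 0) unless
    ``allow_decreasing`` is set.

    Raises
    ------
    UnfittableError
        When the response range is below ``rel_noise_floor`` times its
        magnitude (flat data).
    RuntimeError
        When the optimizer fails to converge.
    """
    if isinstance(curve, ResponseCurve):
        doses, responses = curve.doses, curve.responses
    else:
        doses = np.asarray(curve[0], dtype=float)
        responses = np.asarray(curve[1], dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses differ in length")
    distinct = np.unique(doses)
    if distinct.size < 5 or (distinct > 0).sum() < 4:
        raise ValueError("need >= 5 distinct doses, >= 4 of them positive")
    span = float(responses.max() - responses.min())
    scale = max(abs(float(responses.max())), abs(float(responses.min())), 1e-300)
    if span <= rel_noise_floor * scale:
        raise UnfittableError("responses are flat: no dose dependence to fit")

    def model(theta, x):
        a, b, logc, d = theta
        return fourpl_eval(FourPL(a, b, 10.0**logc, d), x)

    def resid(theta):
        return model(theta, doses) - responses

    theta0 = np.array(_initial_guess(doses, responses))
    b_lo = -20.0 if allow_decreasing else 0.05
    lo = np.array([-np.inf, b_lo, -30.0, -np.inf])
    hi = np.array([np.inf, 20.0, 10.0, np.inf])
    theta0[1] = np.clip(theta0[1], b_lo + 1e-6, 20.0 - 1e-6)
    res = least_squares(
        resid,
        theta0,
        bounds=(lo, hi),
        loss="soft_l1" if robust else "linear",
        f_scale=0.1 * span if robust else 1.0,
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=5000,
    )
    if not res.success:
        raise RuntimeError(f"4PL fit did not converge: {res.message}")
    a, b, logc, d = res.x
    fit = FourPL(float(a), float(b), float(10.0**logc), float(d))
    predicted = fourpl_eval(fit, doses)
    return fit, r_squared(responses, predicted)


def curve_metrics(p: FourPL, basal_floor: float = 0.0) -> CurveMetrics:
    """Derived characteristics of a fitted activating 4PL.

    ``basal_floor`` guards the reciprocal-basal metrics when the fitted
    minimum asymptote is at (or below) zero: basal = max(A, basal_floor).

    Raises
    ------
    ValueError
        If D <= A (inverted curve).
    """
    if p.D <= p.A:
        raise ValueError("curve is inverted (D <= A); not an activating fit")
    basal = max(p.A, basal_floor)
    emax = p.D
    sens = math.nan
    target = 2.0 * basal
    if p.A < target < p.D:
        sens = _invert_fourpl(p, target)
    span = (2.0 / abs(p.B)) * math.log10(19.0)
    tight = 1.0 / basal if basal > 0 else math.inf
    dyn = emax / basal if basal > 0 else math.inf
    return CurveMetrics(
        logEC50=math.log10(p.C),
        hill_slope=p.B,
        sensitivity=sens,
        operational_range_orders=span,
        tightness=tight,
        dynamic_range=dyn,
        basal=basal,
        emax=emax,
    )


def _invert_fourpl(p: FourPL, y: float) -> float:
    """Dose at which the 4PL takes the value ``y`` in the open (A, D)."""
    return p.C * ((p.A - p.D) / (y - p.D) - 1.0) ** (1.0 / p.B)


def growth_rate(series: GrowthSeries, t: float, window_h: float = 3.0) -> float:
    """Per-hour growth rate ln(OD(t+3h)/OD(t)) / 3 from an OD600 series.

    OD is interpolated log-linearly between samples. Raises ValueError when
    ``t`` or ``t + window_h`` falls outside the series.
    """
    t0, t1 = float(t), float(t) + window_h
    if t0 < series.times[0] or t1 > series.times[-1]:
        raise ValueError(
            f"window [{t0}, {t1}] h outside series range "
            f"[{series.times[0]}, {series.times[-1]}] h"
        )
    log_od = np.log(series.od600)
    l0 = float(np.interp(t0, series.times, log_od))
    l1 = float(np.interp(t1, series.times, log_od))
    return (l1 - l0) / window_h


def r_squared(observed, predicted) -> ResidualSet:
    """Residuals e_i = y_i - f_i and the coefficient of determination.

    R^2 = 1 - sum(e^2) / sum((y - ybar)^2). Raises ValueError on mismatched
    lengths, fewer than two points, or zero total variance.
    """
    y = np.asarray(observed, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if y.shape != f.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be matching 1-D arrays")
    if y.size < 2:
        raise ValueError("need at least two points")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values are all equal: zero total variance")
    e = y - f
    r2 = 1.0 - float(np.sum(e**2)) / sst
    return ResidualSet(observed=y, predicted=f, residuals=e, r_squared=r2)


def compose_mixture(spec: MixtureSpec, dose_grid) -> ResponseCurve:
    """Population response of a consortium on ``dose_grid``.

    Each dose's response is the weight-averaged response of the member
    strains, modelling unnormalised total-culture fluorescence of a mixed
    population (members may be :class:`ResponseCurve`, resampled log-linearly,
    or :class:`FourPL`, evaluated exactly).
    """
    grid = np.asarray(dose_grid, dtype=float)
    total = np.zeros(grid.shape, dtype=float)
    for member, w in zip(spec.members, spec.weights):
        if isinstance(member, FourPL):
            vals = fourpl_eval(member, grid)
        elif isinstance(member, ResponseCurve):
            vals = member.interpolate(grid)
        else:
            raise TypeError(f"unsupported mixture member type: {type(member)!r}")
        total += w * np.atleast_1d(vals)
    return ResponseCurve(doses=grid, responses=total, label="mixture")


def span_fold_change(span1_orders: float, span2_orders: float) -> float:
    """Fold-change between two operational ranges given in orders of magnitude.

    Returns 10**(span2 - span1): the ratio of the concentration-fold ranges.
    """
    if span1_orders <= 0 or span2_orders <= 0:
        raise ValueError("spans must be positive")
    return 10.0 ** (span2_orders - span1_orders)
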