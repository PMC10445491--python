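"""Initial-velocity extraction and IC50 dose-response fitting.

Velocities are the ordinary-least-squares slopes of RFU vs time over the
linear window of each progress curve.  Inhibition is the normalized ratio
(v_control − v_treated)/v_control, and IC50 comes from a two-parameter
logistic (bottom fixed at 0, top at 1) fitted on log-concentration:

    inhibition(c) = c^h / (c^h + IC50^h)

The two-parameter form is used because the inhibition ratio is already
normalized to the uninhibited control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import DesignError, InvalidParameterError, UnreliableFitError
from .synthetic import KineticTrace


@dataclass
class RateMeasurement:
    """Initial velocity (RFU/min) with its standard error and fit window."""

    velocity: float
    se: float
    r_squared: float
    window: tuple[float, float]
    flagged: bool = False


@dataclass
class DoseResponseResult:
    ic50: float
    hill: float
    ic50_ci: tuple[float, float]
    r_squared: float
    n_points: int


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, slope SE, r² of y on x.  r²=1 for an exact fit."""
    n = x.size
    coef, res_arr, *_ = np.polyfit(x, y, 1, full=True)[:2]
    slope, intercept = coef
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    scale = max(float(np.sum(y**2)), 1.0)
    if ss_res <= 1e-20 * scale:
        r2 = 1.0
    elif ss_tot == 0:
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    sxx = float(np.sum((x - x.mean()) ** 2))
    se = np.sqrt(ss_res / (n - 2) / sxx) if (n > 2 and sxx > 0) else 0.0
    return float(slope), float(intercept), se, max(min(r2, 1.0), 0.0)


def estimate_velocity(trace: KineticTrace, r2_threshold: float = 0.98) -> RateMeasurement:
    """OLS slope of RFU vs time over the linear window.

    The window starts as the full read and shrinks from the end, one point
    at a time, until r² ≥ ``r2_threshold`` or only 4 points remain (the
    result is then flagged).  Fewer than 4 points is an error.
    """
    t, y = trace.times, trace.rfu
    if t.size < 4:
        raise DesignError("velocity estimation needs at least 4 time points")
    for end in range(t.size, 3, -1):
        slope, _, se, r2 = _ols_line(t[:end], y[:end])
        if r2 >= r2_threshold:
            return RateMeasurement(slope, se, r2, (float(t[0]), float(t[end - 1])))
    slope, _, se, r2 = _ols_line(t[:4], y[:4])
    return RateMeasurement(slope, se, r2, (float(t[0]), float(t[3])), flagged=True)


def percent_inhibition(v_control: float, v_treated: float) -> float:
    """(v_control − v_treated)/v_control, unclipped (negative = activation)."""
    if v_control <= 0:
        raise InvalidParameterError("control velocity must be positive")
    return (v_control - v_treated) / v_control


def _logistic_log10(logc: np.ndarray, log_ic50: float, hill: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (hill * (log_ic50 - logc)))


def fit_ic50(
    concentrations,
    inhibitions,
    pool_replicates: bool = False,
) -> DoseResponseResult:
    """Fit the two-parameter logistic to (concentration, inhibition) data.

    Repeated concentrations are treated as replicates and averaged before
    fitting unless ``pool_replicates`` is set.  Zero concentrations are
    controls, not fit points.  Requires ≥ 4 distinct positive
    concentrations and at least one inhibition inside [0.3, 0.7] so that
    the 50% point is bracketed; the fit is on log10 concentration with the
    confidence interval taken from the parameter covariance.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(inhibitions, dtype=float)
    if c.shape != y.shape:
        raise InvalidParameterError("concentrations and inhibitions must align")
    mask = c > 0
    c, y = c[mask], y[mask]
    if np.unique(c).size < 4:
        raise DesignError("need at least 4 distinct positive concentrations")
    if not pool_replicates:
        uniq = np.unique(c)
        y = np.array([y[c == u].mean() for u in uniq])
        c = uniq
    if np.all(y < 0.3) or np.all(y > 0.7):
        raise UnreliableFitError(
            "inhibition data do not bracket the 50% point; IC50 is unconstrained"
        )
    logc = np.log10(c)
    p0 = (float(logc[np.argmin(np.abs(y - 0.5))]), 1.0)
    popt, pcov = optimize.curve_fit(_logistic_log10, logc, y, p0=p0, maxfev=10000)
    log_ic50, hill = popt
    fitted = _logistic_log10(logc, *popt)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_res <= 1e-20 else (1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    se_log = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.inf
    ic50 = 10.0**log_ic50
    ci = (10.0 ** (log_ic50 - 1.96 * se_log), 10.0 ** (log_ic50 + 1.96 * se_log))
    return DoseResponseResult(
        ic50=float(ic50),
        hill=float(hill),
        ic50_ci=(float(ci[0]), float(ci[1])),
        r_squared=float(max(min(r2, 1.0), 0.0)),
        n_points=int(c.size),
    )
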