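"""Slow-binding inhibition analysis from preincubation decay data.

When an inhibitor associates slowly, preincubating it with the enzyme
depletes activity exponentially:

    v/v0 = exp(−Kobs·t)                                (activity decay)
    Kobs = k4·(1 + [I]/Ki_app)                         (linear in [I])
    Ki_app = k4/k3

so the Kobs-vs-[I] line has intercept k4 (the off-rate) and slope
k4/Ki_app = k3 (the on-rate, µM⁻¹·min⁻¹).  Ki_app is derived from the
fitted constants as k4/k3 so the three reported numbers are mutually
consistent by construction.

All computation uses minutes.  Published tables sometimes label the slope
s⁻¹ while the intercept is min⁻¹; with mixed labels the ratio k4/k3 is only
an equilibrium constant if both share a time unit, so a unit warning is
attached to results rather than silently rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .dose_response import estimate_velocity
from .errors import DesignError, NotSlowBindingError
from .synthetic import KineticTrace

UNIT_NOTE = (
    "all rate constants are in minute units (k3: uM^-1 min^-1, k4: min^-1); "
    "verify unit labels before comparing with tables printed in s^-1"
)


@dataclass
class PreincubationSeries:
    """Residual-activity ratios v/v0 at one inhibitor level."""

    inhibitor: float
    times: np.ndarray
    v_over_v0: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.v_over_v0 = np.asarray(self.v_over_v0, dtype=float)
        if not np.any(self.times == 0):
            raise DesignError("preincubation series must include t=0")
        if np.any(self.v_over_v0 <= 0):
            raise DesignError("v/v0 must be positive for exponential-decay fitting")


@dataclass
class KobsFit:
    kobs: float
    se: float
    flagged: bool = False


@dataclass
class SlowBindingResult:
    kobs_per_inhibitor: pd.DataFrame  # inhibitor_uM, kobs, se
    k3: float  # uM^-1 min^-1 (slope)
    k3_se: float
    k4: float  # min^-1 (intercept)
    k4_se: float
    ki_app: float  # uM, = k4/k3 by construction
    line_r_squared: float
    flagged: bool = False
    note: str = UNIT_NOTE


def fit_kobs(series: PreincubationSeries) -> KobsFit:
    """Nonlinear least-squares fit of v/v0 = exp(−Kobs·t), Kobs ≥ 0.

    A series trending upward (best Kobs negative) is flagged and returned
    with Kobs = 0 rather than reporting an unphysical negative rate.
    """
    t, y = series.times, series.v_over_v0
    if t.size < 4:
        raise DesignError("Kobs fit needs at least 4 time points")
    # unconstrained trend on the log scale decides the flag
    trend = np.polyfit(t, np.log(y), 1)[0]
    if trend > 0:
        return KobsFit(kobs=0.0, se=np.nan, flagged=True)
    if trend == 0:  # exactly flat: v/v0 ≡ const, no measurable decay
        return KobsFit(kobs=0.0, se=0.0)
    k0 = -trend
    popt, pcov = optimize.curve_fit(
        lambda tt, k: np.exp(-k * tt), t, y, p0=(k0,), bounds=(0.0, np.inf), maxfev=10000
    )
    se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.nan
    return KobsFit(kobs=float(popt[0]), se=se)


def fit_rate_constants(kobs_table: pd.DataFrame) -> SlowBindingResult:
    """k3, k4 and Ki_app from the straight line Kobs = k4 + k3·[I].

    ``kobs_table`` needs columns ``inhibitor_uM`` and ``kobs`` and
    optionally ``se``; when every SE is finite and positive the regression
    is weighted by 1/se², otherwise ordinary least squares is used.  The
    slope is k3 (since k4/Ki_app = k3) and the intercept k4; Ki_app = k4/k3
    so the identity Ki_app·k3 = k4 holds to machine precision.  A
    non-positive slope means Kobs does not grow with [I] — not slow-binding
    — and raises; a non-positive intercept leaves Ki_app undefined
    (flagged).
    """
    required = {"inhibitor_uM", "kobs"}
    if not required.issubset(kobs_table.columns):
        raise DesignError(f"kobs table needs columns {sorted(required)}")
    tab = kobs_table.sort_values("inhibitor_uM", ignore_index=True)
    x = tab["inhibitor_uM"].to_numpy(dtype=float)
    y = tab["kobs"].to_numpy(dtype=float)
    if np.unique(x).size < 3 or not np.any(x == 0):
        raise DesignError("need >= 3 inhibitor levels including 0")

    weights = None
    if "se" in tab.columns:
        se = tab["se"].to_numpy(dtype=float)
        if np.all(np.isfinite(se)) and np.all(se > 0):
            weights = 1.0 / se**2
    X = sm.add_constant(x)
    model = sm.WLS(y, X, weights=weights) if weights is not None else sm.OLS(y, X)
    res = model.fit()
    k4, k3 = float(res.params[0]), float(res.params[1])
    k4_se, k3_se = float(res.bse[0]), float(res.bse[1])
    if k3 <= 0:
        raise NotSlowBindingError(
            "Kobs does not increase with inhibitor concentration; "
            "no slow-binding association rate can be estimated"
        )
    flagged = False
    if k4 <= 0:
        ki_app = np.nan
        flagged = True
    else:
        ki_app = k4 / k3
    return SlowBindingResult(
        kobs_per_inhibitor=tab,
        k3=k3, k3_se=k3_se, k4=k4, k4_se=k4_se,
        ki_app=float(ki_app),
        line_r_squared=float(res.rsquared),
        flagged=flagged,
    )


def analyze_preincubation(
    data: pd.DataFrame,
) -> SlowBindingResult:
    """Full slow-binding analysis from a v/v0 table.

    ``data`` needs columns ``inhibitor_uM``, ``preincubation_min`` and
    ``v_over_v0`` (replicates as repeated rows); Kobs is fitted per
    inhibitor level and the constants from the Kobs line.
    """
    rows = []
    for i_level, sub in data.groupby("inhibitor_uM"):
        series = PreincubationSeries(
            inhibitor=float(i_level),
            times=sub["preincubation_min"].to_numpy(dtype=float),
            v_over_v0=sub["v_over_v0"].to_numpy(dtype=float),
        )
        fit = fit_kobs(series)
        rows.append({"inhibitor_uM": float(i_level), "kobs": fit.kobs, "se": fit.se})
    return fit_rate_constants(pd.DataFrame(rows))


def time_dependence_profile(traces: list[KineticTrace]) -> pd.DataFrame:
    """Residual activity velocity(t_pre)/velocity(0) per preincubation time.

    Traces are grouped by their ``preincubation`` annotation; a zero
    -preincubation group must exist.  The returned table carries a
    ``monotone_decline`` diagnostic column (True when the profile never
    increases, within 1%).
    """
    groups: dict[float, list[float]] = {}
    for tr in traces:
        groups.setdefault(float(tr.preincubation), []).append(
            estimate_velocity(tr).velocity
        )
    if 0.0 not in groups:
        raise DesignError("time-dependence profile requires a zero-preincubation group")
    v0 = float(np.mean(groups[0.0]))
    times = sorted(groups)
    ratios = [float(np.mean(groups[t])) / v0 for t in times]
    monotone = bool(np.all(np.diff(ratios) <= 0.01))
    return pd.DataFrame(
        {
            "preincubation_min": times,
            "residual_activity": ratios,
            "monotone_decline": monotone,
        }
    )
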