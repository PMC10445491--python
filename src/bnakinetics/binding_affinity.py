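"""Binding affinity from intrinsic-fluorescence quenching titrations.

The enzyme's tryptophan/tyrosine emission (peak near 340 nm) is quenched as
ligand is titrated in.  Two standard analyses are provided:

* Stern-Volmer:  F0/F = 1 + KSV·[Q]; KSV is the slope of (F0/F − 1) vs [Q]
  through the origin.
* Double-log:    log10[(F0 − F)/F] = log10 KA + n·log10[Q]; the intercept
  gives the affinity constant KA and the slope the number of binding
  sites n.

Free quencher is approximated by total quencher (the enzyme is at trace
concentration).  Internally concentrations are µM, so KSV is µM⁻¹ and KA
µM⁻ⁿ; the conventional L·mol⁻¹ reporting scale is obtained with the 10⁶
factor (applied as if n = 1 for KA, which is flagged because KA's formal
unit depends on n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, InvalidParameterError

#: 1 µM⁻¹ = 10⁶ L·mol⁻¹
UM_INV_TO_L_PER_MOL = 1.0e6


@dataclass
class PeakResult:
    intensity: float
    wavelength: float
    flagged: bool = False


@dataclass
class QuenchTitration:
    """Peak intensities F at each quencher level, with F0 the [Q]=0 value."""

    quencher: np.ndarray
    f: np.ndarray
    f0: float

    def __post_init__(self) -> None:
        self.quencher = np.asarray(self.quencher, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.f0 <= 0 or np.any(self.f <= 0):
            raise InvalidParameterError("intensities must be positive")
        if np.unique(self.quencher).size != self.quencher.size:
            raise InvalidParameterError("quencher levels must be distinct")


@dataclass
class QuenchingResult:
    """KSV, KA and n with fit diagnostics and explicit reporting scales."""

    ksv: float  # µM⁻¹
    ksv_r2: float
    ka: float  # µM⁻ⁿ
    n_sites: float
    ka_r2: float
    ka_scale_note: str = (
        "ka_1e6_L_per_mol applies the 10^6 uM->L/mol factor as if n=1; "
        "KA's formal unit is uM^-n"
    )

    @property
    def ksv_1e5_L_per_mol(self) -> float:
        """KSV on the ×10⁵ L·mol⁻¹ reporting scale."""
        return self.ksv * UM_INV_TO_L_PER_MOL / 1e5

    @property
    def ka_1e6_L_per_mol(self) -> float:
        """KA on the ×10⁶ L·mol⁻¹ reporting scale (numerically the µM⁻ⁿ value)."""
        return self.ka * UM_INV_TO_L_PER_MOL / 1e6


def extract_peak(wavelengths, intensities) -> PeakResult:
    """Maximum intensity over an emission scan and its wavelength.

    A flat spectrum returns its constant value at the first wavelength,
    flagged as degenerate.  Requires at least 10 scan points.
    """
    wl = np.asarray(wavelengths, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if wl.size == 0 or y.size == 0:
        raise DesignError("empty spectrum")
    if wl.size < 10:
        raise DesignError("spectrum needs at least 10 wavelength points")
    if np.allclose(y, y[0]):
        return PeakResult(float(y[0]), float(wl[0]), flagged=True)
    idx = int(np.argmax(y))
    return PeakResult(float(y[idx]), float(wl[idx]))


def titration_from_spectra(spectra: pd.DataFrame) -> QuenchTitration:
    """Build a peak-intensity titration from a long-format spectra table.

    Needs columns ``quencher_uM``, ``wavelength_nm`` and ``intensity``
    (replicates, if present, are averaged per wavelength first).
    """
    required = {"quencher_uM", "wavelength_nm", "intensity"}
    if not required.issubset(spectra.columns):
        raise DesignError(f"spectra table needs columns {sorted(required)}")
    qs, peaks = [], []
    for q, sub in spectra.groupby("quencher_uM"):
        mean_spec = sub.groupby("wavelength_nm")["intensity"].mean()
        pk = extract_peak(mean_spec.index.to_numpy(), mean_spec.to_numpy())
        qs.append(float(q))
        peaks.append(pk.intensity)
    qs = np.asarray(qs)
    peaks = np.asarray(peaks)
    if not np.any(qs == 0):
        raise DesignError("titration requires a zero-quencher spectrum for F0")
    f0 = float(peaks[qs == 0][0])
    mask = qs > 0
    return QuenchTitration(quencher=qs[mask], f=peaks[mask], f0=f0)


@dataclass
class SternVolmerFit:
    ksv: float
    r2: float
    flagged: bool = False


@dataclass
class DoubleLogFit:
    ka: float
    n_sites: float
    r2: float
    excluded: int = 0


def fit_stern_volmer(titration: QuenchTitration, f_tolerance: float = 0.05) -> SternVolmerFit:
    """KSV as the through-origin slope of (F0/F − 1) vs [Q].

    Points with F above F0 by more than ``f_tolerance`` (relative) flag the
    fit — intensity growing with quencher is inconsistent with quenching.
    """
    q, f = titration.quencher, titration.f
    if q.size < 3:
        raise DesignError("Stern-Volmer fit needs >= 3 nonzero quencher levels")
    flagged = bool(np.any(f > titration.f0 * (1.0 + f_tolerance)))
    y = titration.f0 / f - 1.0
    ksv = float(np.sum(q * y) / np.sum(q * q))
    fitted = ksv * q
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_res <= 1e-20 * max(float(np.sum(y**2)), 1e-30):
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return SternVolmerFit(ksv=ksv, r2=float(max(min(r2, 1.0), 0.0)), flagged=flagged)


def fit_double_log(titration: QuenchTitration) -> DoubleLogFit:
    """(KA, n) from OLS of log10((F0−F)/F) on log10([Q]).

    Points with F ≥ F0 have no defined quenched fraction and are excluded
    with a warning; fewer than 3 usable points is an error.
    """
    q, f = titration.quencher, titration.f
    usable = f < titration.f0
    n_excluded = int(np.sum(~usable))
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} point(s) with F >= F0 from the double-log fit",
            stacklevel=2,
        )
    q, f = q[usable], f[usable]
    if q.size < 3:
        raise DesignError("double-log fit needs >= 3 usable nonzero quencher levels")
    x = np.log10(q)
    y = np.log10((titration.f0 - f) / f)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_res <= 1e-20 * max(float(np.sum(y**2)), 1e-30):
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return DoubleLogFit(
        ka=float(10.0**intercept),
        n_sites=float(slope),
        r2=float(max(min(r2, 1.0), 0.0)),
        excluded=n_excluded,
    )


def analyze_quenching(titration: QuenchTitration) -> QuenchingResult:
    """Run both standard analyses on one titration."""
    sv = fit_stern_volmer(titration)
    dl = fit_double_log(titration)
    return QuenchingResult(
        ksv=sv.ksv, ksv_r2=sv.r2, ka=dl.ka, n_sites=dl.n_sites, ka_r2=dl.r2
    )
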