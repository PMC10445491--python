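"""Steady-state Michaelis-Menten rate laws for reversible inhibition.

All concentrations are in µM, velocities in RFU/min.  The four classical
single-substrate inhibition mechanisms are parameterized as

* competitive:      v = Vmax·S / (Km·(1 + I/Ki) + S)
* noncompetitive:   v = Vmax·S / ((Km + S)·(1 + I/Ki))
* uncompetitive:    v = Vmax·S / (Km + S·(1 + I/Ki))
* mixed:            v = Vmax·S / (Km·(1 + I/Ki) + S·(1 + I/(α·Ki)))

``mode="none"`` is the uninhibited Michaelis-Menten law.  Pure
noncompetitive inhibition is the α = 1 special case of mixed; competitive
is the α → ∞ limit.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError

MODES = ("competitive", "noncompetitive", "uncompetitive", "mixed", "none")

#: number of free parameters fitted for each candidate law (Vmax, Km, Ki[, alpha])
N_PARAMS = {"competitive": 3, "noncompetitive": 3, "uncompetitive": 3, "mixed": 4}

#: tie-break preference, fewest-assumption mechanism first
PREFERENCE = ("competitive", "noncompetitive", "uncompetitive", "mixed")


def velocity(
    mode: str,
    substrate,
    inhibitor,
    vmax: float,
    km: float,
    ki: float | None = None,
    alpha: float = 1.0,
):
    """Evaluate the mode-specific inhibited rate.

    Parameters
    ----------
    mode
        One of :data:`MODES`.
    substrate, inhibitor
        Concentrations in µM (scalars or arrays, broadcast together).
    vmax
        Limiting velocity in RFU/min.
    km
        Michaelis constant in µM.
    ki
        Inhibition constant in µM; required for every mode except ``"none"``.
    alpha
        Mixed-mode factor (>0); the ES-complex binding constant is α·Ki.
    """
    if mode not in MODES:
        raise InvalidParameterError(f"unknown inhibition mode {mode!r}")
    if km <= 0 or vmax <= 0:
        raise InvalidParameterError(f"Km and Vmax must be positive (got {km}, {vmax})")
    s = np.asarray(substrate, dtype=float)
    i = np.asarray(inhibitor, dtype=float)
    if mode == "none":
        return vmax * s / (km + s)
    if ki is None or ki <= 0:
        raise InvalidParameterError(f"mode {mode!r} requires Ki > 0 (got {ki})")
    if alpha <= 0:
        raise InvalidParameterError(f"alpha must be positive (got {alpha})")
    f = i / ki
    if mode == "competitive":
        return vmax * s / (km * (1.0 + f) + s)
    if mode == "noncompetitive":
        return vmax * s / ((km + s) * (1.0 + f))
    if mode == "uncompetitive":
        return vmax * s / (km + s * (1.0 + f))
    # mixed
    return vmax * s / (km * (1.0 + f) + s * (1.0 + i / (alpha * ki)))
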