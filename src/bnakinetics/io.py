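"""Validated CSV readers for plate-reader kinetics and quench tables.

CSV is the single interchange format; the frozen column sets are

kinetics: experiment_id, replicate, time_min, rfu, substrate_uM,
          inhibitor_uM, enzyme_u_per_mL, preincubation_min
quench:   quencher_uM, wavelength_nm, intensity (optional compound,
          replicate)

Malformed rows are reported with their 1-based data line numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .synthetic import KINETICS_COLUMNS, KineticTrace

_NUMERIC_KINETICS = [c for c in KINETICS_COLUMNS if c != "experiment_id"]
_NONNEGATIVE = ["time_min", "substrate_uM", "inhibitor_uM", "enzyme_u_per_mL",
                "preincubation_min"]

#: columns identifying one physical well within an experiment
WELL_KEY = ["experiment_id", "replicate", "substrate_uM", "inhibitor_uM",
            "enzyme_u_per_mL", "preincubation_min"]


def _load_csv(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty input file") from None
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    bad_rows: list[str] = []
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for idx in bad:
            bad_rows.append(f"line {idx + 2}: non-numeric {col}={df.loc[idx, col]!r}")
        df[col] = coerced
        nan = df.index[df[col].isna()]
        for idx in nan:
            if idx not in bad:
                bad_rows.append(f"line {idx + 2}: missing {col}")
    if bad_rows:
        raise ParseError(f"{path}: malformed rows:\n  " + "\n  ".join(bad_rows[:20]))
    return df


def read_kinetics_csv(path) -> dict[str, list[KineticTrace]]:
    """Read and validate a kinetics CSV, grouped by experiment_id.

    Each (experiment, replicate, condition) well becomes one
    :class:`KineticTrace` with its readings sorted by time.
    """
    df = _load_csv(path, KINETICS_COLUMNS, _NUMERIC_KINETICS)
    bad_rows = []
    for col in _NONNEGATIVE:
        for idx in df.index[df[col] < 0]:
            bad_rows.append(f"line {idx + 2}: negative {col}={df.loc[idx, col]}")
    dup = df.duplicated(subset=WELL_KEY + ["time_min"], keep=False)
    if dup.any():
        first = df.index[dup][:10]
        bad_rows += [f"line {i + 2}: duplicated (well, time) reading" for i in first]
    if bad_rows:
        raise ParseError(f"{path}: malformed rows:\n  " + "\n  ".join(bad_rows[:20]))

    # well key order: (experiment_id, replicate, S, I, E, preincubation)
    out: dict[str, list[KineticTrace]] = {}
    for key, sub in df.groupby(WELL_KEY, sort=True):
        sub = sub.sort_values("time_min")
        exp_id = str(key[0])
        out.setdefault(exp_id, []).append(
            KineticTrace(
                times=sub["time_min"].to_numpy(),
                rfu=sub["rfu"].to_numpy(),
                substrate=float(key[2]),
                inhibitor=float(key[3]),
                enzyme=float(key[4]),
                preincubation=float(key[5]),
                replicate=int(key[1]),
                experiment_id=exp_id,
            )
        )
    return out


def read_quench_csv(path) -> pd.DataFrame:
    """Read and validate a quench-spectra CSV (long format)."""
    df = _load_csv(
        path,
        ["quencher_uM", "wavelength_nm", "intensity"],
        ["quencher_uM", "wavelength_nm", "intensity"],
    )
    bad = df.index[df["quencher_uM"] < 0]
    if len(bad):
        rows = "\n  ".join(f"line {i + 2}: negative quencher_uM" for i in bad[:20])
        raise ParseError(f"{path}: malformed rows:\n  {rows}")
    if "compound" not in df.columns:
        df = df.assign(compound="sample")
    return df
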