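"""End-to-end analysis: raw CSVs in, per-compound result tables out.

Experiment ids in the kinetics CSV follow ``<compound>:<stage>`` where the
stage is one of ``dose``, ``grid``, ``reversibility`` or ``slowbinding``.
Each stage feeds its estimator; a failure in one compound/stage is recorded
and the pipeline continues.  Given the same inputs and seed the result
CSVs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding_affinity, dose_response, mode_kinetics, slow_binding
from .config import StudyConfig
from .errors import BnaKineticsError
from .io import read_kinetics_csv, read_quench_csv
from .synthetic import KineticTrace

STAGES = ("dose", "grid", "reversibility", "slowbinding")


@dataclass
class ReportBundle:
    ic50_table: pd.DataFrame
    mode_table: pd.DataFrame
    reversibility_table: pd.DataFrame
    slow_binding_table: pd.DataFrame
    quenching_table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        named = {
            "ic50.csv": self.ic50_table,
            "mode.csv": self.mode_table,
            "reversibility.csv": self.reversibility_table,
            "slow_binding.csv": self.slow_binding_table,
            "quenching.csv": self.quenching_table,
        }
        for name, df in named.items():
            df.to_csv(out / name, index=False, float_format="%.10g")
        (out / "warnings.txt").write_text("\n".join(self.warnings + self.errors) + "\n")


def _split_id(experiment_id: str) -> tuple[str, str]:
    if ":" not in experiment_id:
        return experiment_id, "dose"
    compound, stage = experiment_id.rsplit(":", 1)
    return compound, stage


def _velocities(traces: list[KineticTrace], cfg: StudyConfig) -> pd.DataFrame:
    rows = []
    for tr in traces:
        rm = dose_response.estimate_velocity(tr, r2_threshold=cfg.linearity_r2)
        rows.append(
            {
                "substrate_uM": tr.substrate,
                "inhibitor_uM": tr.inhibitor,
                "enzyme_u_per_mL": tr.enzyme,
                "preincubation_min": tr.preincubation,
                "replicate": tr.replicate,
                "velocity": rm.velocity,
                "flagged": rm.flagged,
            }
        )
    return pd.DataFrame(rows)


def _analyze_dose(traces, cfg: StudyConfig) -> dict:
    vel = _velocities(traces, cfg)
    controls = vel.loc[vel["inhibitor_uM"] == 0, "velocity"]
    if controls.empty:
        raise BnaKineticsError("dose stage has no zero-inhibitor control wells")
    v0 = float(controls.mean())
    sub = vel[vel["inhibitor_uM"] > 0]
    inh = [dose_response.percent_inhibition(v0, v) for v in sub["velocity"]]
    fit = dose_response.fit_ic50(sub["inhibitor_uM"].to_numpy(), np.asarray(inh))
    return {
        "ic50_uM": fit.ic50,
        "ic50_ci_low": fit.ic50_ci[0],
        "ic50_ci_high": fit.ic50_ci[1],
        "hill": fit.hill,
        "r2": fit.r_squared,
        "n_points": fit.n_points,
    }


def _analyze_grid(traces, cfg: StudyConfig) -> dict:
    vel = _velocities(traces, cfg)
    agg = (
        vel.groupby(["substrate_uM", "inhibitor_uM"])["velocity"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    se = agg["std"] / np.sqrt(agg["count"])
    se = se.where(np.isfinite(se) & (se > 0), other=np.nan)
    grid = mode_kinetics.RateGrid(
        agg["substrate_uM"].to_numpy(),
        agg["inhibitor_uM"].to_numpy(),
        agg["mean"].to_numpy(),
        se.to_numpy() if se.notna().all() else None,
    )
    fit = mode_kinetics.fit_global_inhibition(grid, score_margin=cfg.mode_score_margin)
    row = {
        "mode": fit.mode,
        "ki_uM": fit.ki,
        "ki_se": fit.ki_se,
        "alpha": fit.alpha if fit.alpha is not None else np.nan,
        "vmax": fit.vmax,
        "km_uM": fit.km,
        "flagged": fit.flagged,
    }
    for m, s in fit.scores.items():
        row[f"score_{m}"] = s
    try:
        ki_dixon, _ = mode_kinetics.dixon_ki(grid)
        row["ki_dixon_uM"] = ki_dixon
    except BnaKineticsError:
        row["ki_dixon_uM"] = np.nan
    try:
        lb = mode_kinetics.lineweaver_burk(grid)
        row["lb_y_intercept_cv"] = lb.y_intercept_cv
        row["lb_x_intercept_cv"] = lb.x_intercept_cv
    except BnaKineticsError:
        row["lb_y_intercept_cv"] = np.nan
        row["lb_x_intercept_cv"] = np.nan
    return row


def _analyze_reversibility(traces, cfg: StudyConfig) -> dict:
    vel = _velocities(traces, cfg)
    res = mode_kinetics.reversibility_test(vel, z_threshold=cfg.intercept_z)
    return {
        "verdict": res.verdict,
        "max_abs_intercept_z": float(res.table["intercept_z"].abs().max()),
        "n_inhibitor_levels": len(res.table),
    }


def _analyze_slowbinding(traces, cfg: StudyConfig) -> dict:
    vel = _velocities(traces, cfg)
    rows = []
    for (i_level, rep), sub in vel.groupby(["inhibitor_uM", "replicate"]):
        base = sub.loc[sub["preincubation_min"] == 0, "velocity"]
        if base.empty:
            raise BnaKineticsError("slow-binding stage missing t=0 preincubation wells")
        v0 = float(base.mean())
        for _, r in sub.iterrows():
            rows.append(
                {
                    "inhibitor_uM": i_level,
                    "preincubation_min": r["preincubation_min"],
                    "v_over_v0": r["velocity"] / v0,
                }
            )
    res = slow_binding.analyze_preincubation(pd.DataFrame(rows))
    return {
        "k3_per_uM_min": res.k3,
        "k3_se": res.k3_se,
        "k4_per_min": res.k4,
        "k4_se": res.k4_se,
        "ki_app_uM": res.ki_app,
        "line_r2": res.line_r_squared,
        "flagged": res.flagged,
        "note": res.note,
    }


def run_pipeline(
    config: StudyConfig,
    kinetics_path=None,
    quench_path=None,
    out_dir=None,
) -> ReportBundle:
    """Analyze a whole study; returns (and optionally writes) all tables."""
    ic50_rows, mode_rows, rev_rows, slow_rows, quench_rows = [], [], [], [], []
    warnings_list: list[str] = []
    errors: list[str] = []

    if kinetics_path is not None:
        experiments = read_kinetics_csv(kinetics_path)
        by_compound: dict[str, dict[str, list[KineticTrace]]] = {}
        for exp_id, traces in experiments.items():
            compound, stage = _split_id(exp_id)
            if stage not in STAGES:
                warnings_list.append(f"{exp_id}: unknown stage {stage!r}, skipped")
                continue
            by_compound.setdefault(compound, {})[stage] = traces
        analyzers = {
            "dose": (_analyze_dose, ic50_rows),
            "grid": (_analyze_grid, mode_rows),
            "reversibility": (_analyze_reversibility, rev_rows),
            "slowbinding": (_analyze_slowbinding, slow_rows),
        }
        for compound in sorted(by_compound):
            for stage, (fn, sink) in analyzers.items():
                if stage not in by_compound[compound]:
                    continue
                try:
                    row = {"compound": compound}
                    row.update(fn(by_compound[compound][stage], config))
                    sink.append(row)
                except BnaKineticsError as exc:
                    errors.append(f"{compound}:{stage}: {exc}")

    if quench_path is not None:
        spectra = read_quench_csv(quench_path)
        for compound, sub in spectra.groupby("compound"):
            try:
                tit = binding_affinity.titration_from_spectra(sub)
                res = binding_affinity.analyze_quenching(tit)
                quench_rows.append(
                    {
                        "compound": compound,
                        "ksv_1e5_L_per_mol": res.ksv_1e5_L_per_mol,
                        "ksv_r2": res.ksv_r2,
                        "ka_1e6_L_per_mol": res.ka_1e6_L_per_mol,
                        "n": res.n_sites,
                        "ka_r2": res.ka_r2,
                    }
                )
            except BnaKineticsError as exc:
                errors.append(f"{compound}:quench: {exc}")

    bundle = ReportBundle(
        ic50_table=pd.DataFrame(ic50_rows),
        mode_table=pd.DataFrame(mode_rows),
        reversibility_table=pd.DataFrame(rev_rows),
        slow_binding_table=pd.DataFrame(slow_rows),
        quenching_table=pd.DataFrame(quench_rows),
        warnings=warnings_list,
        errors=errors,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
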