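"""Synthetic fluorometric assay generator with known ground truth.

Emulates a plate-reader study of bacterial neuraminidase (BNA) inhibition
with the MUNANA fluorogenic substrate: linear progress curves read every
minute for 20 min, substrate at 0.5×/1×/2× Km (Km = 100 µM), inhibitor at
0.5×/1×/2× IC50, enzyme at 0.01/0.02/0.04 unit/mL, preincubation decay
series, and tryptophan-emission quenching scans from 300 to 400 nm in 2-nm
steps.  Every generator draws multiplicative Gaussian noise with a stated
coefficient of variation (default 2%, three replicates) from a single seed,
so identical inputs give bit-identical output and noiseless runs are exact.

The generators exist so that every downstream estimator in the package can
be validated by parameter recovery: simulate with a known truth, fit, and
compare.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import ratelaws
from .errors import DesignError, InvalidParameterError

#: enzyme concentration (unit/mL) at which truth.vmax is defined; velocities
#: scale linearly as enzyme/REFERENCE_ENZYME (the assay's standard load)
REFERENCE_ENZYME = 0.02

#: default emission scan grid, nm
DEFAULT_WAVELENGTHS = np.arange(300.0, 400.0 + 1e-9, 2.0)

#: emission peak centre and width (nm) of the synthetic tryptophan band
PEAK_NM = 340.0
PEAK_WIDTH_NM = 18.0

KINETICS_COLUMNS = [
    "experiment_id",
    "replicate",
    "time_min",
    "rfu",
    "substrate_uM",
    "inhibitor_uM",
    "enzyme_u_per_mL",
    "preincubation_min",
]

QUENCH_COLUMNS = ["compound", "quencher_uM", "wavelength_nm", "replicate", "intensity"]


@dataclass
class AssayTruth:
    """Ground-truth parameters for one simulated compound/enzyme system.

    Only the parameters of the experiment class being generated need to be
    set; e.g. ``k3``/``k4`` are required by :func:`simulate_slow_binding`
    but ignored by the dose-response generator.

    Units: concentrations µM; ``vmax`` RFU/min at the reference enzyme
    load; ``k3`` µM⁻¹·min⁻¹; ``k4`` min⁻¹; ``ksv`` µM⁻¹; ``ka`` µM⁻ⁿ;
    ``f0`` RFU.
    """

    km: float = 100.0
    vmax: float = 200.0
    mode: str = "none"
    ki: float | None = None
    alpha: float = 1.0
    ic50: float | None = None
    hill: float = 1.0
    k3: float | None = None
    k4: float | None = None
    ksv: float | None = None
    ka: float | None = None
    n_sites: float = 1.0
    f0: float = 1000.0

    def __post_init__(self) -> None:
        if self.km <= 0 or self.vmax <= 0:
            raise InvalidParameterError("Km and Vmax must be strictly positive")
        if self.mode not in ratelaws.MODES:
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if self.alpha <= 0:
            raise InvalidParameterError("alpha must be strictly positive")
        if self.mode != "none" and (self.ki is None or self.ki <= 0):
            raise InvalidParameterError(f"mode {self.mode!r} requires Ki > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AssayTruth":
        return cls(**d)


@dataclass
class NoiseSpec:
    """Replicate count and multiplicative noise level for a generator run.

    ``cv`` is the coefficient of variation of the multiplicative Gaussian
    noise applied to every simulated reading; ``cv=0`` gives exact values.
    """

    cv: float = 0.02
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise InvalidParameterError("cv must be non-negative")
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


NOISELESS = NoiseSpec(cv=0.0, replicates=1, seed=0)


@dataclass
class KineticTrace:
    """One well's progress curve plus its assay annotations."""

    times: np.ndarray
    rfu: np.ndarray
    substrate: float
    inhibitor: float
    enzyme: float
    preincubation: float = 0.0
    replicate: int = 0
    experiment_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.times.shape != self.rfu.shape:
            raise InvalidParameterError("times and rfu must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        for name in ("substrate", "inhibitor", "enzyme", "preincubation"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")


def _noisy(values: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Gaussian noise: x·(1 + cv·N(0,1)). Exact when cv=0."""
    values = np.asarray(values, dtype=float)
    if cv == 0:
        return values.copy()
    return values * (1.0 + cv * rng.standard_normal(values.shape))


def simulate_progress_trace(
    truth: AssayTruth,
    substrate: float,
    inhibitor: float,
    enzyme: float,
    noise: NoiseSpec,
    times: Sequence[float] | None = None,
    baseline: float = 50.0,
    activity: float = 1.0,
    experiment_id: str = "",
) -> list[KineticTrace]:
    """Simulate linear progress curves RFU(t) = baseline + v·t (+ noise).

    The slope v is the mode-specific inhibited Michaelis-Menten rate scaled
    linearly by enzyme load relative to :data:`REFERENCE_ENZYME`
    (initial-rate regime, no substrate depletion).  ``activity`` scales the
    rate further, e.g. exp(−Kobs·t_pre) after a preincubation.  Returns one
    trace per replicate.
    """
    if substrate <= 0:
        raise InvalidParameterError("substrate must be positive")
    if enzyme <= 0:
        raise InvalidParameterError("enzyme must be positive")
    if times is None:
        times = np.arange(0.0, 21.0, 1.0)  # 1-min reads for 20 min
    times = np.asarray(times, dtype=float)
    v = float(
        ratelaws.velocity(
            truth.mode, substrate, inhibitor, truth.vmax, truth.km, truth.ki, truth.alpha
        )
    )
    v *= (enzyme / REFERENCE_ENZYME) * activity
    rng = noise.rng()
    traces = []
    for rep in range(noise.replicates):
        rfu = baseline + _noisy(v * times, noise.cv, rng)
        traces.append(
            KineticTrace(
                times=times,
                rfu=rfu,
                substrate=substrate,
                inhibitor=inhibitor,
                enzyme=enzyme,
                replicate=rep,
                experiment_id=experiment_id,
            )
        )
    return traces


def dose_inhibition(truth: AssayTruth, concentration) -> np.ndarray:
    """Noiseless fractional inhibition c^h/(c^h + IC50^h)."""
    if truth.ic50 is None or truth.ic50 <= 0:
        raise InvalidParameterError("dose-response generation requires IC50 > 0")
    c = np.asarray(concentration, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(c > 0, c**truth.hill / (c**truth.hill + truth.ic50**truth.hill), 0.0)
    return out


def simulate_dose_response(
    truth: AssayTruth, concentrations: Sequence[float], noise: NoiseSpec
) -> pd.DataFrame:
    """Simulate fractional-inhibition measurements at each concentration.

    Requires a zero-concentration control.  Noise is multiplicative, so the
    control stays exactly 0; values are reported unclipped (noise can push
    an inhibition slightly above 1 or below 0 at the extremes).
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise InvalidParameterError("concentrations must be non-negative")
    if not np.any(conc == 0):
        raise DesignError("dose series must include a zero-concentration control")
    clean = dose_inhibition(truth, conc)
    rng = noise.rng()
    rows = []
    for rep in range(noise.replicates):
        vals = _noisy(clean, noise.cv, rng)
        for c, y in zip(conc, vals):
            rows.append({"concentration_uM": c, "replicate": rep, "inhibition": y})
    return pd.DataFrame(rows)


def simulate_reversibility(
    truth: AssayTruth,
    enzyme_levels: Sequence[float],
    inhibitor_levels: Sequence[float],
    noise: NoiseSpec,
) -> pd.DataFrame:
    """Velocity vs enzyme load at each inhibitor level (reversible model).

    v([E], [I]) = rate_law([S]=Km, [I]) · [E]/E_ref — a straight line
    through the origin in [E], whose slope shrinks with [I].
    """
    enzymes = np.asarray(enzyme_levels, dtype=float)
    if np.any(enzymes <= 0):
        raise InvalidParameterError("enzyme levels must be positive")
    inhibitors = np.asarray(inhibitor_levels, dtype=float)
    rng = noise.rng()
    rows = []
    for rep in range(noise.replicates):
        for i_conc in inhibitors:
            v0 = float(
                ratelaws.velocity(
                    truth.mode, truth.km, i_conc, truth.vmax, truth.km, truth.ki, truth.alpha
                )
            )
            v = _noisy(v0 * enzymes / REFERENCE_ENZYME, noise.cv, rng)
            for e_conc, vel in zip(enzymes, v):
                rows.append(
                    {
                        "enzyme_u_per_mL": e_conc,
                        "inhibitor_uM": i_conc,
                        "replicate": rep,
                        "velocity": vel,
                    }
                )
    return pd.DataFrame(rows)


def slow_binding_kobs(truth: AssayTruth, inhibitor) -> np.ndarray:
    """Kobs([I]) = k4·(1 + [I]/Ki_app) with Ki_app = k4/k3, i.e. k4 + k3·[I]."""
    if truth.k3 is None or truth.k3 <= 0 or truth.k4 is None or truth.k4 <= 0:
        raise InvalidParameterError("slow-binding generation requires k3 > 0 and k4 > 0")
    i = np.asarray(inhibitor, dtype=float)
    ki_app = truth.k4 / truth.k3
    return truth.k4 * (1.0 + i / ki_app)


def simulate_slow_binding(
    truth: AssayTruth,
    inhibitors: Sequence[float],
    preincubation_times: Sequence[float],
    noise: NoiseSpec,
) -> pd.DataFrame:
    """Residual-activity ratios v/v0 = exp(−Kobs·t_pre) per inhibitor level.

    The decay has no steady-state plateau; at t=0 the noiseless ratio is
    exactly 1.
    """
    times = np.asarray(preincubation_times, dtype=float)
    if not np.any(times == 0):
        raise DesignError("preincubation series must include t=0")
    inhibitors = np.asarray(inhibitors, dtype=float)
    kobs = slow_binding_kobs(truth, inhibitors)
    rng = noise.rng()
    rows = []
    for rep in range(noise.replicates):
        for i_conc, k in zip(inhibitors, kobs):
            ratios = _noisy(np.exp(-k * times), noise.cv, rng)
            for t, r in zip(times, ratios):
                rows.append(
                    {
                        "inhibitor_uM": i_conc,
                        "preincubation_min": t,
                        "replicate": rep,
                        "v_over_v0": r,
                    }
                )
    return pd.DataFrame(rows)


def quench_peak_intensity(truth: AssayTruth, model: str, quencher) -> np.ndarray:
    """Peak intensity F([Q]) under the chosen quenching model.

    ``stern_volmer``: F = F0/(1 + KSV·[Q]);  ``double_log``: F = F0/(1 +
    KA·[Q]^n), the inversion of log[(F0−F)/F] = log KA + n·log[Q].  Free
    quencher is approximated by total quencher (trace enzyme).
    """
    q = np.asarray(quencher, dtype=float)
    if truth.f0 is None or truth.f0 <= 0:
        raise InvalidParameterError("quenching generation requires F0 > 0")
    if model == "stern_volmer":
        if truth.ksv is None or truth.ksv < 0:
            raise InvalidParameterError("stern_volmer model requires KSV >= 0")
        return truth.f0 / (1.0 + truth.ksv * q)
    if model == "double_log":
        if truth.ka is None or truth.ka <= 0 or truth.n_sites <= 0:
            raise InvalidParameterError("double_log model requires KA > 0 and n > 0")
        return truth.f0 / (1.0 + truth.ka * q**truth.n_sites)
    raise InvalidParameterError(f"unknown quenching model {model!r}")


def simulate_quenching(
    truth: AssayTruth,
    model: str,
    quencher: Sequence[float],
    noise: NoiseSpec,
    wavelengths: Sequence[float] | None = None,
    compound: str = "sample",
) -> pd.DataFrame:
    """Emission spectra (300–400 nm) whose peak titrates with quencher.

    Each spectrum is a smooth Gaussian band centred at 340 nm whose peak
    intensity follows the chosen quenching model.
    """
    q = np.asarray(quencher, dtype=float)
    if np.any(q < 0):
        raise InvalidParameterError("quencher concentrations must be non-negative")
    if not np.any(q == 0):
        raise DesignError("quencher series must include a zero control (F0)")
    if wavelengths is None:
        wavelengths = DEFAULT_WAVELENGTHS
    wavelengths = np.asarray(wavelengths, dtype=float)
    peaks = quench_peak_intensity(truth, model, q)
    profile = np.exp(-0.5 * ((wavelengths - PEAK_NM) / PEAK_WIDTH_NM) ** 2)
    rng = noise.rng()
    rows = []
    for rep in range(noise.replicates):
        for qc, fpk in zip(q, peaks):
            spec = _noisy(fpk * profile, noise.cv, rng)
            for wl, inten in zip(wavelengths, spec):
                rows.append(
                    {
                        "compound": compound,
                        "quencher_uM": qc,
                        "wavelength_nm": wl,
                        "replicate": rep,
                        "intensity": inten,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file output and whole-study generation
# ---------------------------------------------------------------------------


def traces_to_frame(traces: Iterable[KineticTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for t, y in zip(tr.times, tr.rfu):
            rows.append(
                {
                    "experiment_id": tr.experiment_id,
                    "replicate": tr.replicate,
                    "time_min": t,
                    "rfu": y,
                    "substrate_uM": tr.substrate,
                    "inhibitor_uM": tr.inhibitor,
                    "enzyme_u_per_mL": tr.enzyme,
                    "preincubation_min": tr.preincubation,
                }
            )
    return pd.DataFrame(rows, columns=KINETICS_COLUMNS)


def write_kinetics_csv(traces: Iterable[KineticTrace] | pd.DataFrame, path) -> None:
    """Write the long-format kinetics CSV the readers and CLI consume."""
    df = traces if isinstance(traces, pd.DataFrame) else traces_to_frame(traces)
    df.to_csv(path, index=False)


def write_quench_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_truth_sidecar(truths: dict[str, AssayTruth], path) -> None:
    """Record generating parameters (JSON) for later recovery checks."""
    payload = {name: truth.to_dict() for name, truth in truths.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_truth_sidecar(path) -> dict[str, AssayTruth]:
    payload = json.loads(Path(path).read_text())
    return {name: AssayTruth.from_dict(d) for name, d in payload.items()}


@dataclass
class StudyDesign:
    """Concentration/time grids for a full simulated study of one compound.

    Defaults follow the study protocol: substrate at 0.5×/1×/2× Km,
    inhibitor at 0.5×/1×/2× IC50 (plus the 0 control), enzyme at
    0.01/0.02/0.04 unit/mL, preincubation 0–10 min in 2-min steps, and
    quencher 0–3.2 µM doublings.
    """

    substrate_factors: tuple = (0.5, 1.0, 2.0)
    inhibitor_factors: tuple = (0.0, 0.5, 1.0, 2.0)
    enzyme_levels: tuple = (0.01, 0.02, 0.04)
    dose_factors: tuple = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
    preincubation_times: tuple = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    slow_inhibitors: tuple = (0.0, 0.2, 0.4, 0.8)
    quencher_levels: tuple = (0.0, 0.2, 0.4, 0.8, 1.6, 3.2)
    quench_model: str = "double_log"


def generate_study(
    truths: dict[str, AssayTruth],
    noise: NoiseSpec,
    design: StudyDesign | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a complete multi-compound study: kinetics + quench tables.

    Kinetics experiment ids follow ``<compound>:<stage>`` with stages
    ``dose``, ``grid``, ``reversibility`` and ``slowbinding``; the slow
    -binding stage is emitted only for truths carrying (k3, k4), and the
    quench table only for truths carrying the quench-model parameters.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(noise.seed)
    kinetics_frames: list[pd.DataFrame] = []
    quench_frames: list[pd.DataFrame] = []

    def stage_noise() -> NoiseSpec:
        # independent stream per stage, all derived from the one study seed
        return NoiseSpec(cv=noise.cv, replicates=noise.replicates,
                         seed=int(rng.integers(0, 2**31 - 1)))

    for name, truth in truths.items():
        if truth.ic50 is None:
            raise InvalidParameterError(f"{name}: study generation requires an IC50 truth")
        # dose-response: control + doublings bracketing the IC50, measured as
        # progress traces whose slope is scaled by (1 - inhibition)
        sn = stage_noise()
        concs = [0.0] + [f * truth.ic50 for f in design.dose_factors]
        traces: list[KineticTrace] = []
        for c in concs:
            inh = float(dose_inhibition(truth, c))
            traces += simulate_progress_trace(
                AssayTruth(km=truth.km, vmax=truth.vmax, mode="none"),
                substrate=truth.km,
                inhibitor=c,
                enzyme=REFERENCE_ENZYME,
                noise=NoiseSpec(sn.cv, sn.replicates, sn.seed + int(round(c * 1e6)) % 10007),
                activity=1.0 - inh,
                experiment_id=f"{name}:dose",
            )
        kinetics_frames.append(traces_to_frame(traces))

        # mode grid: substrate × inhibitor factorial
        sn = stage_noise()
        traces = []
        for j, s_f in enumerate(design.substrate_factors):
            for k, i_f in enumerate(design.inhibitor_factors):
                traces += simulate_progress_trace(
                    truth,
                    substrate=s_f * truth.km,
                    inhibitor=i_f * truth.ic50,
                    enzyme=REFERENCE_ENZYME,
                    noise=NoiseSpec(sn.cv, sn.replicates, sn.seed + 101 * j + k),
                    experiment_id=f"{name}:grid",
                )
        kinetics_frames.append(traces_to_frame(traces))

        # reversibility: enzyme × inhibitor, line through the origin
        sn = stage_noise()
        traces = []
        for j, e in enumerate(design.enzyme_levels):
            for k, i_f in enumerate(design.inhibitor_factors):
                traces += simulate_progress_trace(
                    truth,
                    substrate=truth.km,
                    inhibitor=i_f * truth.ic50,
                    enzyme=e,
                    noise=NoiseSpec(sn.cv, sn.replicates, sn.seed + 101 * j + k),
                    experiment_id=f"{name}:reversibility",
                )
        kinetics_frames.append(traces_to_frame(traces))

        # slow binding: preincubation decay traces
        if truth.k3 is not None and truth.k4 is not None:
            sn = stage_noise()
            traces = []
            kobs = slow_binding_kobs(truth, np.asarray(design.slow_inhibitors))
            for j, (i_conc, k) in enumerate(zip(design.slow_inhibitors, kobs)):
                for m, tpre in enumerate(design.preincubation_times):
                    reps = simulate_progress_trace(
                        truth,
                        substrate=truth.km,
                        inhibitor=i_conc,
                        enzyme=REFERENCE_ENZYME,
                        noise=NoiseSpec(sn.cv, sn.replicates, sn.seed + 101 * j + m),
                        activity=float(np.exp(-k * tpre)),
                        experiment_id=f"{name}:slowbinding",
                    )
                    for tr in reps:
                        tr.preincubation = tpre
                    traces += reps
            kinetics_frames.append(traces_to_frame(traces))

        # quenching titration
        if (design.quench_model == "stern_volmer" and truth.ksv is not None) or (
            design.quench_model == "double_log" and truth.ka is not None
        ):
            sn = stage_noise()
            quench_frames.append(
                simulate_quenching(
                    truth,
                    design.quench_model,
                    design.quencher_levels,
                    sn,
                    compound=name,
                )
            )

    kinetics = pd.concat(kinetics_frames, ignore_index=True)
    quench = (
        pd.concat(quench_frames, ignore_index=True)
        if quench_frames
        else pd.DataFrame(columns=QUENCH_COLUMNS)
    )
    return kinetics, quench
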