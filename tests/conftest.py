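import numpy as np
import pytest

from bnakinetics import AssayTruth, NoiseSpec

# Truths used throughout: a potent competitive slow-binding inhibitor and a
# weaker noncompetitive one, with their quenching parameters.
COMPOUND1 = dict(
    km=100.0, vmax=200.0, mode="competitive", ki=0.17, ic50=0.38,
    k3=0.1410, k4=0.0203, ksv=0.15792, ka=0.24434, n_sites=1.2897,
)
COMPOUND4 = dict(
    km=100.0, vmax=200.0, mode="noncompetitive", ki=4.2, ic50=3.8,
    ksv=0.02714, ka=0.05545, n_sites=0.7819,
)


@pytest.fixture
def compound1() -> AssayTruth:
    return AssayTruth(**COMPOUND1)


@pytest.fixture
def compound4() -> AssayTruth:
    return AssayTruth(**COMPOUND4)


@pytest.fixture
def noiseless() -> NoiseSpec:
    return NoiseSpec(cv=0.0, replicates=1, seed=0)


@pytest.fixture
def triplicate() -> NoiseSpec:
    return NoiseSpec(cv=0.02, replicates=3, seed=20260922)


def grid_arrays(mode, ki, substrate_levels, inhibitor_levels, vmax=200.0, km=100.0,
                alpha=1.0):
    """Noiseless factorial velocity grid from a rate law (test helper)."""
    from bnakinetics import ratelaws

    S, I = np.meshgrid(substrate_levels, inhibitor_levels, indexing="ij")
    v = ratelaws.velocity(mode, S, I, vmax, km, ki, alpha)
    return S.ravel(), I.ravel(), v.ravel()
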