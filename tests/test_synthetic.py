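"""Generator correctness: closed-form slopes, determinism, monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnakinetics import (
    AssayTruth,
    NoiseSpec,
    simulate_dose_response,
    simulate_progress_trace,
    simulate_quenching,
    simulate_reversibility,
    simulate_slow_binding,
)
from bnakinetics.errors import DesignError, InvalidParameterError
from bnakinetics.synthetic import (
    REFERENCE_ENZYME,
    dose_inhibition,
    quench_peak_intensity,
    slow_binding_kobs,
)


def slope_of(trace):
    return np.polyfit(trace.times, trace.rfu, 1)[0]


class TestProgressTrace:
    def test_uninhibited_slope_is_half_vmax_at_km(self, noiseless):
        truth = AssayTruth(km=100, vmax=200, mode="none")
        (tr,) = simulate_progress_trace(truth, 100.0, 0.0, REFERENCE_ENZYME, noiseless)
        assert slope_of(tr) == pytest.approx(100.0, rel=1e-12)

    def test_competitive_slope_at_ki_and_km_is_vmax_third(self, noiseless):
        truth = AssayTruth(km=100, vmax=200, mode="competitive", ki=0.5)
        (tr,) = simulate_progress_trace(truth, 100.0, 0.5, REFERENCE_ENZYME, noiseless)
        assert slope_of(tr) == pytest.approx(200.0 / 3.0, rel=1e-12)

    @pytest.mark.parametrize("substrate", [50.0, 100.0, 200.0])
    def test_noncompetitive_at_ki_halves_slope_at_any_substrate(self, substrate, noiseless):
        inh = AssayTruth(km=100, vmax=200, mode="noncompetitive", ki=2.0)
        ctl = AssayTruth(km=100, vmax=200, mode="none")
        (tr_i,) = simulate_progress_trace(inh, substrate, 2.0, REFERENCE_ENZYME, noiseless)
        (tr_0,) = simulate_progress_trace(ctl, substrate, 0.0, REFERENCE_ENZYME, noiseless)
        assert slope_of(tr_i) == pytest.approx(slope_of(tr_0) / 2.0, rel=1e-12)

    def test_slope_scales_linearly_with_enzyme(self, noiseless):
        truth = AssayTruth(km=100, vmax=200, mode="none")
        slopes = [
            slope_of(simulate_progress_trace(truth, 100.0, 0.0, e, noiseless)[0])
            for e in (0.01, 0.02, 0.04)
        ]
        assert slopes[1] == pytest.approx(2 * slopes[0], rel=1e-12)
        assert slopes[2] == pytest.approx(4 * slopes[0], rel=1e-12)

    def test_invalid_parameters_raise(self, noiseless):
        truth = AssayTruth(km=100, vmax=200, mode="none")
        with pytest.raises(InvalidParameterError):
            simulate_progress_trace(truth, -1.0, 0.0, 0.02, noiseless)
        with pytest.raises(InvalidParameterError):
            AssayTruth(km=100, vmax=200, mode="competitive", ki=-1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        ki=st.floats(0.05, 50.0),
        i_lo=st.floats(0.01, 5.0),
        factor=st.floats(1.1, 10.0),
        mode=st.sampled_from(["competitive", "noncompetitive", "uncompetitive", "mixed"]),
    )
    def test_velocity_strictly_decreasing_in_inhibitor(self, ki, i_lo, factor, mode):
        noiseless = NoiseSpec(cv=0.0, replicates=1, seed=0)
        truth = AssayTruth(km=100, vmax=200, mode=mode, ki=ki, alpha=2.0)
        (lo,) = simulate_progress_trace(truth, 100.0, i_lo, 0.02, noiseless)
        (hi,) = simulate_progress_trace(truth, 100.0, i_lo * factor, 0.02, noiseless)
        assert slope_of(hi) < slope_of(lo)


class TestDoseResponse:
    def test_half_inhibition_at_ic50_and_zero_at_control(self, noiseless):
        truth = AssayTruth(ic50=1.0, hill=1.0)
        df = simulate_dose_response(truth, [0.0, 1.0, 3.0], noiseless)
        by_c = df.set_index("concentration_uM")["inhibition"]
        assert by_c[0.0] == 0.0
        assert by_c[1.0] == pytest.approx(0.5, abs=1e-15)
        assert by_c[3.0] == pytest.approx(0.75, abs=1e-15)

    def test_missing_control_raises(self, noiseless):
        with pytest.raises(DesignError):
            simulate_dose_response(AssayTruth(ic50=1.0), [0.5, 1.0, 2.0], noiseless)


class TestReversibility:
    def test_velocity_ratios_follow_enzyme_levels(self, noiseless):
        truth = AssayTruth(km=100, vmax=200, mode="none")
        df = simulate_reversibility(truth, [0.01, 0.02, 0.04], [0.0], noiseless)
        v = df.sort_values("enzyme_u_per_mL")["velocity"].to_numpy()
        assert v[1] == pytest.approx(2 * v[0], rel=1e-12)
        assert v[2] == pytest.approx(4 * v[0], rel=1e-12)

    def test_noncompetitive_at_ki_halves_slope_vs_enzyme(self, noiseless):
        truth = AssayTruth(km=100, vmax=200, mode="noncompetitive", ki=1.0)
        df = simulate_reversibility(truth, [0.01, 0.02, 0.04], [0.0, 1.0], noiseless)
        slope = {
            i: np.polyfit(sub["enzyme_u_per_mL"], sub["velocity"], 1)[0]
            for i, sub in df.groupby("inhibitor_uM")
        }
        assert slope[1.0] == pytest.approx(slope[0.0] / 2.0, rel=1e-12)


class TestSlowBinding:
    def test_kobs_at_zero_inhibitor_is_k4(self):
        truth = AssayTruth(ic50=0.38, k3=0.1410, k4=0.0203)
        assert slow_binding_kobs(truth, 0.0) == pytest.approx(0.0203, rel=1e-15)

    def test_kobs_at_printed_constants(self):
        # Kobs = k4·(1 + [I]/(k4/k3)) evaluated at [I] = 0.8 µM
        truth = AssayTruth(ic50=0.38, k3=0.1410, k4=0.0203)
        expected = 0.0203 * (1.0 + 0.8 / (0.0203 / 0.1410))
        assert slow_binding_kobs(truth, 0.8) == pytest.approx(expected, rel=1e-12)

    def test_ratio_is_one_at_t0_and_strictly_decreasing(self, noiseless):
        truth = AssayTruth(ic50=0.38, k3=0.1410, k4=0.0203)
        df = simulate_slow_binding(truth, [0.4], [0, 2, 4, 6, 8, 10], noiseless)
        r = df.sort_values("preincubation_min")["v_over_v0"].to_numpy()
        assert r[0] == 1.0
        assert np.all(np.diff(r) < 0)

    def test_invalid_rate_constants_raise(self, noiseless):
        truth = AssayTruth(ic50=0.38, k3=-0.1, k4=0.02)
        with pytest.raises(InvalidParameterError):
            simulate_slow_binding(truth, [0, 0.2], [0, 2, 4], noiseless)


class TestQuenching:
    def test_peak_is_f0_at_zero_quencher(self, noiseless):
        truth = AssayTruth(ksv=0.15792, f0=1000.0)
        df = simulate_quenching(truth, "stern_volmer", [0.0, 0.4, 3.2], noiseless)
        spec0 = df[df.quencher_uM == 0]
        assert spec0["intensity"].max() == pytest.approx(1000.0, rel=1e-12)

    def test_stern_volmer_peak_ratio_at_printed_ksv(self):
        truth = AssayTruth(ksv=0.15792, f0=1000.0)
        f = quench_peak_intensity(truth, "stern_volmer", 3.2)
        assert 1000.0 / f == pytest.approx(1.0 + 0.15792 * 3.2, rel=1e-12)

    def test_models_coincide_when_n_is_one(self, noiseless):
        truth = AssayTruth(ksv=0.2, ka=0.2, n_sites=1.0, f0=1000.0)
        q = [0.0, 0.2, 0.8, 3.2]
        sv = simulate_quenching(truth, "stern_volmer", q, noiseless)
        dl = simulate_quenching(truth, "double_log", q, noiseless)
        np.testing.assert_allclose(sv["intensity"], dl["intensity"], rtol=1e-12)

    def test_negative_quencher_raises(self, noiseless):
        with pytest.raises(InvalidParameterError):
            simulate_quenching(AssayTruth(ksv=0.1), "stern_volmer", [0, -1.0], noiseless)


class TestDeterminism:
    def test_identical_inputs_give_bit_identical_output(self):
        truth = AssayTruth(ic50=0.38, k3=0.1410, k4=0.0203)
        noise = NoiseSpec(cv=0.02, replicates=3, seed=42)
        a = simulate_slow_binding(truth, [0, 0.2, 0.4], [0, 2, 4, 6], noise)
        b = simulate_slow_binding(truth, [0, 0.2, 0.4], [0, 2, 4, 6], noise)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        truth = AssayTruth(ic50=0.38)
        a = simulate_dose_response(truth, [0, 0.38], NoiseSpec(0.05, 3, 1))
        b = simulate_dose_response(truth, [0, 0.38], NoiseSpec(0.05, 3, 2))
        assert not np.allclose(a["inhibition"], b["inhibition"])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(ic50=st.floats(0.05, 50.0), c_factor=st.floats(0.1, 10.0))
def test_dose_inhibition_matches_hill_formula(ic50, c_factor):
    truth = AssayTruth(ic50=ic50, hill=1.0)
    c = ic50 * c_factor
    assert dose_inhibition(truth, c) == pytest.approx(c / (c + ic50), rel=1e-12)
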