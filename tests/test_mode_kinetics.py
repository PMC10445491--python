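"""Mode classification, Lineweaver-Burk/Dixon geometry, reversibility."""

import numpy as np
import pandas as pd
import pytest

from bnakinetics import (
    AssayTruth,
    NoiseSpec,
    RateGrid,
    dixon_ki,
    fit_global_inhibition,
    fit_ic50,
    lineweaver_burk,
    reversibility_test,
    simulate_reversibility,
)
from bnakinetics import ratelaws
from bnakinetics.errors import DesignError, NoIntersectionError
from conftest import grid_arrays

S_LEVELS = [50.0, 100.0, 200.0]


def make_grid(mode, ki, inhibitor_levels, alpha=1.0):
    return RateGrid(*grid_arrays(mode, ki, S_LEVELS, inhibitor_levels, alpha=alpha))


class TestGlobalFit:
    @pytest.mark.parametrize(
        "mode, ki, ilev, alpha",
        [
            ("competitive", 0.17, [0, 0.19, 0.38, 0.76], 1.0),
            ("noncompetitive", 4.2, [0, 1.9, 3.8, 7.6], 1.0),
            ("uncompetitive", 1.0, [0, 0.5, 1.0, 2.0], 1.0),
            ("mixed", 1.0, [0, 0.5, 1.0, 2.0], 3.0),
        ],
    )
    def test_noiseless_confusion_matrix_identity(self, mode, ki, ilev, alpha):
        fit = fit_global_inhibition(make_grid(mode, ki, ilev, alpha))
        assert fit.mode == mode
        assert fit.ki == pytest.approx(ki, rel=1e-6)
        if mode == "mixed":
            assert fit.alpha == pytest.approx(alpha, rel=1e-4)

    def test_no_inhibition_grid_flagged_degenerate(self):
        S, I, _ = grid_arrays("competitive", 1.0, S_LEVELS, [0, 0.5, 1.0])
        v = ratelaws.velocity("none", S, 0.0, 200.0, 100.0)
        fit = fit_global_inhibition(RateGrid(S, I, v))
        assert fit.mode == "none"
        assert np.isinf(fit.ki)
        assert fit.flagged

    def test_apparent_parameters_follow_competitive_geometry(self):
        fit = fit_global_inhibition(make_grid("competitive", 0.17, [0, 0.19, 0.38, 0.76]))
        app = fit.apparent.sort_values("inhibitor_uM")
        # Vmax unchanged, apparent Km grows with [I]
        np.testing.assert_allclose(app["vmax_app"], 200.0, rtol=1e-6)
        assert np.all(np.diff(app["km_app"]) > 0)

    def test_noisy_classification_rate(self):
        # with triplicate 2% noise the true mode should win almost always
        rng = np.random.default_rng(99)
        correct = 0
        n_rep = 50
        for _ in range(n_rep):
            S, I, v = grid_arrays("noncompetitive", 4.2, S_LEVELS, [0, 1.9, 3.8, 7.6])
            vn = np.mean(
                [v * (1 + 0.02 * rng.standard_normal(v.shape)) for _ in range(3)], axis=0
            )
            fit = fit_global_inhibition(RateGrid(S, I, vn))
            correct += fit.mode == "noncompetitive"
        assert correct / n_rep >= 0.9


class TestLineweaverBurk:
    def test_uninhibited_intercepts_are_reciprocal_constants(self):
        # the [I]=0 line of any grid is plain Michaelis-Menten:
        # y-intercept 1/Vmax, x-intercept -1/Km
        grid = make_grid("competitive", 0.17, [0, 0.19, 0.38])
        res = lineweaver_burk(grid)
        line0 = res.lines[0.0]
        assert line0.y_intercept == pytest.approx(1.0 / 200.0, rel=1e-9)
        assert line0.x_intercept == pytest.approx(-1.0 / 100.0, rel=1e-9)

    def test_competitive_lines_share_y_intercept(self):
        res = lineweaver_burk(make_grid("competitive", 0.17, [0, 0.19, 0.38, 0.76]))
        y_ints = [ln.y_intercept for ln in res.lines.values()]
        np.testing.assert_allclose(y_ints, 1.0 / 200.0, rtol=1e-9)
        assert res.y_intercept_cv < 1e-9

    def test_noncompetitive_lines_share_x_intercept(self):
        res = lineweaver_burk(make_grid("noncompetitive", 4.2, [0, 1.9, 3.8, 7.6]))
        x_ints = [ln.x_intercept for ln in res.lines.values()]
        np.testing.assert_allclose(x_ints, -1.0 / 100.0, rtol=1e-9)
        assert res.x_intercept_cv < 1e-9


class TestDixon:
    def test_competitive_intersection_gives_ki(self):
        ki, _ = dixon_ki(make_grid("competitive", 0.17, [0, 0.19, 0.38, 0.76]))
        assert ki == pytest.approx(0.17, rel=1e-9)

    def test_noncompetitive_intersection_on_axis_gives_ki(self):
        grid = make_grid("noncompetitive", 4.2, [0, 1.9, 3.8, 7.6])
        ki, table = dixon_ki(grid)
        assert ki == pytest.approx(4.2, rel=1e-9)
        # intersection lies on the [I]-axis: 1/v there equals 0 within rounding
        m, c = np.polyfit(
            grid.inhibitor[grid.substrate == 100.0],
            1.0 / grid.velocity[grid.substrate == 100.0],
            1,
        )
        assert m * (-4.2) + c == pytest.approx(0.0, abs=1e-12)

    def test_uncompetitive_parallel_lines_raise(self):
        grid = make_grid("uncompetitive", 1.0, [0, 0.5, 1.0, 2.0])
        with pytest.raises(NoIntersectionError):
            dixon_ki(grid)

    def test_dixon_agrees_with_global_fit_within_one_percent(self):
        for mode, ki, ilev in [
            ("competitive", 0.17, [0, 0.19, 0.38, 0.76]),
            ("noncompetitive", 4.2, [0, 1.9, 3.8, 7.6]),
        ]:
            grid = make_grid(mode, ki, ilev)
            ki_glob = fit_global_inhibition(grid).ki
            ki_dix, _ = dixon_ki(grid)
            assert ki_dix == pytest.approx(ki_glob, rel=0.01)


class TestChengPrusoff:
    def test_competitive_ic50_is_twice_ki_at_km(self):
        # velocities at [S]=Km over an inhibitor titration -> logistic with
        # IC50 = Ki·(1 + S/Km) = 2·Ki
        ki = 0.17
        i_levels = ki * 2.0 ** np.arange(-2, 6, dtype=float)
        v = ratelaws.velocity("competitive", 100.0, i_levels, 200.0, 100.0, ki)
        v0 = float(ratelaws.velocity("none", 100.0, 0.0, 200.0, 100.0))
        inh = (v0 - v) / v0
        res = fit_ic50(i_levels, inh)
        assert res.ic50 == pytest.approx(2 * ki, rel=1e-4)

    def test_noncompetitive_ic50_equals_ki(self):
        ki = 4.2
        i_levels = ki * 2.0 ** np.arange(-3, 5, dtype=float)
        v = ratelaws.velocity("noncompetitive", 100.0, i_levels, 200.0, 100.0, ki)
        v0 = float(ratelaws.velocity("none", 100.0, 0.0, 200.0, 100.0))
        inh = (v0 - v) / v0
        res = fit_ic50(i_levels, inh)
        assert res.ic50 == pytest.approx(ki, rel=1e-4)


class TestReversibility:
    def test_noiseless_reversible_generator_output(self, noiseless):
        truth = AssayTruth(km=100, vmax=200, mode="competitive", ki=0.17)
        df = simulate_reversibility(truth, [0.01, 0.02, 0.04], [0, 0.19, 0.38], noiseless)
        res = reversibility_test(df)
        assert res.verdict == "reversible"
        np.testing.assert_allclose(res.table["intercept"], 0.0, atol=1e-10)

    def test_constant_offset_flips_verdict(self, noiseless):
        truth = AssayTruth(km=100, vmax=200, mode="competitive", ki=0.17)
        df = simulate_reversibility(truth, [0.01, 0.02, 0.04], [0, 0.19, 0.38], noiseless)
        df["velocity"] += 20.0
        assert reversibility_test(df).verdict == "irreversible-like"

    def test_slope_ratio_matches_rate_law_factor(self, noiseless):
        ki = 1.0
        truth = AssayTruth(km=100, vmax=200, mode="noncompetitive", ki=ki)
        df = simulate_reversibility(truth, [0.01, 0.02, 0.04], [0.0, ki], noiseless)
        res = reversibility_test(df)
        tab = res.table.set_index("inhibitor_uM")
        assert res.verdict == "reversible"
        assert tab.loc[ki, "slope"] == pytest.approx(tab.loc[0.0, "slope"] / 2, rel=1e-9)

    def test_too_few_enzyme_levels_raise(self):
        df = pd.DataFrame(
            {"enzyme_u_per_mL": [0.01, 0.02], "inhibitor_uM": 0.0, "velocity": [1.0, 2.0]}
        )
        with pytest.raises(DesignError):
            reversibility_test(df)
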