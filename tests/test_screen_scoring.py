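"""Scoring statistics: fold changes, AUC scores, QC, classes, Spearman."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cox2screen import synthetic_screen as ss
from cox2screen.reporter_kinetics import presets, simulate_well
from cox2screen.screen_scoring import (
    ScoringConfig,
    autofluorescence_qc,
    classify,
    confluency_score,
    control_mean_series,
    fold_change_series,
    gfp_score,
    spearman,
)


def series(values, times=None):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values), dtype=float) * 2.0
    return pd.Series(values, index=np.asarray(times, dtype=float))


class TestControlMean:
    def test_identical_controls_return_common_series(self):
        rows = [("P1", f"W{i}", "dmso_control", t, 5.0)
                for i in range(9) for t in (0.0, 2.0)]
        df = pd.DataFrame(rows, columns=["plate", "well", "role", "time_h", "m"])
        out = control_mean_series(df, "dmso_control", "m")
        assert (out == 5.0).all()

    def test_mean_of_three_values(self):
        df = pd.DataFrame({
            "plate": "P1", "well": ["a", "b", "c"], "role": "dmso_control",
            "time_h": 0.0, "m": [1.0, 2.0, 3.0]})
        assert control_mean_series(df, "dmso_control", "m").iloc[0] == 2.0

    def test_missing_role_names_plate(self):
        df = pd.DataFrame({"plate": ["P3"], "well": ["a"], "role": ["compound"],
                           "time_h": [0.0], "m": [1.0]})
        with pytest.raises(ValueError, match="P3"):
            control_mean_series(df, "dmso_control", "m")


class TestFoldChange:
    def test_well_equals_control_gives_ones(self):
        fc = fold_change_series(series([3, 4, 5]), series([3, 4, 5]), 0.05)
        assert (fc == 1.0).all()

    def test_elementwise_ratio(self):
        fc = fold_change_series(series([2, 4]), series([1, 2]), 0.05)
        assert list(fc) == [2.0, 2.0]

    def test_floor_applies_to_zero_control(self):
        fc = fold_change_series(series([0.5]), series([0.0]), 0.05)
        assert fc.iloc[0] == pytest.approx(10.0)

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError, match="grid"):
            fold_change_series(series([1, 2]), series([1, 2], times=[0, 4]), 0.05)


class TestScores:
    def test_flat_unity_curve_scores_one(self):
        fc = series(np.ones(37))
        assert gfp_score(fc) == pytest.approx(1.0)

    def test_linear_ramp_time_normalized(self):
        # FC rising linearly 1 -> 9 over 72 h averages to 5
        t = np.linspace(0, 72, 37)
        fc = series(1 + 8 * t / 72, times=t)
        assert gfp_score(fc) == pytest.approx(5.0)

    def test_linear_ramp_raw_hours(self):
        t = np.linspace(0, 72, 37)
        fc = series(1 + 8 * t / 72, times=t)
        cfg = ScoringConfig(auc_mode="raw_hours")
        assert gfp_score(fc, cfg) == pytest.approx(360.0)

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            gfp_score(series([1.0]))

    def test_confluency_mean(self):
        assert confluency_score(series([1.0, 0.3])) == pytest.approx(0.65)

    def test_confluency_empty_errors(self):
        with pytest.raises(ValueError):
            confluency_score(series([]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.0, 20.0), st.floats(0.0, 10.0)),
                    min_size=2, max_size=8, unique_by=lambda p: p[0]))
    def test_auc_matches_closed_form_for_piecewise_linear(self, knots):
        """Sampling a piecewise-linear curve densely and scoring it
        reproduces the exact segment-sum area."""
        knots = sorted(knots)
        t_knots = np.array([k[0] for k in knots])
        v_knots = np.array([k[1] for k in knots])
        if t_knots[-1] - t_knots[0] < 1e-6:
            return
        t_dense = np.unique(np.concatenate(
            [t_knots, np.linspace(t_knots[0], t_knots[-1], 101)]))
        v_dense = np.interp(t_dense, t_knots, v_knots)
        exact = float(np.sum(np.diff(t_knots)
                             * (v_knots[:-1] + v_knots[1:]) / 2.0))
        cfg = ScoringConfig(auc_mode="raw_hours")
        got = gfp_score(pd.Series(v_dense, index=t_dense), cfg)
        assert got == pytest.approx(exact, rel=1e-9, abs=1e-9)


class TestQC:
    def test_early_jump_flagged(self):
        fc = series([1.0, 5.0, 1.0, 1.0])
        assert autofluorescence_qc(fc) is True

    def test_flat_vehicle_not_flagged(self):
        fc = series(np.ones(37) + 0.01)
        assert autofluorescence_qc(fc) is False

    def test_genuine_slow_inducer_not_flagged(self, grid, dmso_traj):
        """A real inducer (5-FU kinetics) has no reporter rise inside the
        early QC window, unlike an intrinsically fluorescent compound."""
        fu = simulate_well(presets("4T1"), presets("5FU_100uM"), grid)
        fc = fold_change_series(
            series(ss.gcu_from_reporter(fu.g), times=grid),
            series(ss.gcu_from_reporter(dmso_traj.g), times=grid), 0.05)
        assert autofluorescence_qc(fc) is False
        assert gfp_score(fc) > 5.0  # but it is a strong hit overall

    def test_fastest_library_inducer_not_flagged(self, grid, dmso_traj):
        """Even the strongest, fastest-ramping library compound stays under
        the early-window cutoff: induced fluorescence needs transcription,
        translation and maturation first."""
        from cox2screen.reporter_kinetics import DrugEffect

        eff = DrugEffect(arrest=1.0, beta=16.0, tau_ind=4.0, t_death=200.0)
        traj = simulate_well(presets("4T1"), eff, grid)
        fc = fold_change_series(
            series(ss.gcu_from_reporter(traj.g), times=grid),
            series(ss.gcu_from_reporter(dmso_traj.g), times=grid), 0.05)
        early = fc[fc.index <= ScoringConfig().qc_early_window_h]
        # well below the exclusion cutoff of 2, with headroom for noise
        assert early.max() < 0.8 * ScoringConfig().qc_early_fc_cutoff


class TestClassify:
    @pytest.mark.parametrize("gfp,conf,expected", [
        (6.0, 0.5, "arrested_induced"),
        (1.0, 1.0, "inactive"),
        (6.0, 0.9, "induced_only"),
        (1.0, 0.5, "arrested_only"),
        (5.0, 0.65, "inactive"),  # thresholds are strict
    ])
    def test_quadrants(self, gfp, conf, expected):
        assert classify(gfp, conf) == expected

    def test_excluded_overrides(self):
        assert classify(10.0, 0.1, excluded=True) == "excluded"


def brute_force_spearman(x, y):
    """Independent oracle: explicit average ranks + explicit Pearson."""
    def ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


class TestSpearman:
    def test_perfectly_concordant(self):
        rho, p, n = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0) and n == 4

    def test_perfectly_discordant(self):
        rho, _, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_tied_example(self):
        # x=[1,1,2,3] -> ranks [1.5,1.5,3,4]; y=[2,1,1,3] -> [3,1.5,1.5,4]
        rho, _, _ = spearman([1, 1, 2, 3], [2, 1, 1, 3])
        assert rho == pytest.approx(brute_force_spearman([1, 1, 2, 3],
                                                         [2, 1, 1, 3]))

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.integers(4, 8).flatmap(
        lambda n: st.tuples(
            st.lists(st.integers(0, 3), min_size=n, max_size=n),
            st.lists(st.integers(0, 3), min_size=n, max_size=n))))
    def test_matches_brute_force_and_scipy_on_tied_inputs(self, xy):
        x, y = xy
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        rho, p, n = spearman(x, y)
        assert rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_exact_permutation_p_small_n(self):
        """For n < 10 the p value is the exact permutation tail probability."""
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        rho, p, _ = spearman(x, y)
        perms = itertools.permutations(y)
        rhos = [brute_force_spearman(x, list(pm)) for pm in perms]
        expected = np.mean([abs(r) >= abs(rho) - 1e-12 for r in rhos])
        assert p == pytest.approx(expected)

    def test_t_approximation_large_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p, n = spearman(x, y)
        t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=n - 2))
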