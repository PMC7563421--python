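"""Forward equilibrium solve and the three closed-form K_D estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from qmdial import (
    ExperimentConfig,
    check_physical,
    kd_from_lred,
    kd_from_lwhite,
    kd_from_pt,
    solve_equilibrium,
)
from qmdial.errors import (
    InfeasibleMeasurementError,
    NoDetectableBindingError,
    ValidationError,
)


def bisection_oracle(config, kd):
    """Independent solve of the equilibrium: scalar root-find of the binding
    law over the complex concentration tl, using only the raw equations."""
    R, W, pc, t0 = config.red_volume, config.white_volume, config.pc, config.t0
    L = config.l0 * (R + W)
    A = W + pc * R

    def residual(tl):
        lwhite = (L - tl * R) / A
        return tl * kd - (t0 - tl) * pc * lwhite

    tl_hi = min(t0, L / R)
    if kd == 0:
        tl = tl_hi
    else:
        tl = brentq(residual, 0.0, tl_hi, xtol=1e-15, rtol=1e-15)
    lwhite = (L - tl * R) / A
    return lwhite, pc * lwhite + tl


class TestForwardSolve:
    @pytest.mark.parametrize(
        "kd, lwhite, lred, pt",
        [
            (300.0, 23.545, 29.366, 1.247),
            (500.0, 24.081, 27.757, 1.153),
        ],
    )
    def test_reported_partition_values(self, fig_config, kd, lwhite, lred, pt):
        state = solve_equilibrium(fig_config, kd)
        assert round(state.lwhite, 3) == lwhite
        assert round(state.lred, 3) == lred
        assert round(state.pt, 3) == pt

    def test_stoichiometric_limit_kd_zero(self, fig_config):
        # Ligand exceeds protein capacity: all protein complexed, the rest
        # of the ligand equilibrates freely.
        state = solve_equilibrium(fig_config, 0.0)
        assert state.tf == 0.0
        assert state.tl == 80.0
        assert state.lwhite == pytest.approx(5.0)
        assert state.lred == pytest.approx(85.0)
        assert state.pt == pytest.approx(17.0)

    def test_kd_zero_ligand_limited(self):
        # Protein in excess of the ligand budget: every ligand molecule bound.
        config = ExperimentConfig(l0=10, t0=80, red_volume=100, white_volume=300)
        state = solve_equilibrium(config, 0.0)
        assert state.lwhite == 0.0
        assert state.tl == pytest.approx(40.0)  # total ligand / red volume
        assert math.isinf(state.pt)

    def test_no_protein_gives_perfect_equilibration(self, std_config):
        config = ExperimentConfig(l0=50, t0=0, red_volume=100, white_volume=300)
        for kd in (0.0, 1.0, 1e4):
            state = solve_equilibrium(config, kd)
            assert state.lwhite == pytest.approx(50.0)
            assert state.lred == pytest.approx(50.0)
            assert state.pt == pytest.approx(1.0)

    def test_large_kd_approaches_control_ratio(self):
        config = ExperimentConfig(l0=50, t0=80, pc=1.05)
        assert solve_equilibrium(config, 1e9).pt == pytest.approx(1.05, rel=1e-4)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -1.0])
    def test_invalid_kd_rejected(self, std_config, bad):
        with pytest.raises(ValidationError):
            solve_equilibrium(std_config, bad)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"red_volume": 0}, {"white_volume": -5}, {"l0": 0},
            {"t0": -1}, {"pc": 0}, {"l0": float("nan")},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ExperimentConfig(**kwargs)

    def test_oracle_equivalence_random_configs(self):
        """Closed form agrees with a bisection solve of the raw equations to
        1e-9 relative over a broad random sweep of configurations."""
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            config = ExperimentConfig(
                l0=rng.uniform(1, 100),
                t0=rng.uniform(1, 200),
                red_volume=rng.uniform(50, 500),
                white_volume=rng.uniform(50, 500),
                pc=rng.uniform(0.9, 1.1),
            )
            kd = 10 ** rng.uniform(-2, 4)
            state = solve_equilibrium(config, kd)
            lwhite, lred = bisection_oracle(config, kd)
            assert state.lwhite == pytest.approx(lwhite, rel=1e-9)
            assert state.lred == pytest.approx(lred, rel=1e-9)

    def test_conservation_and_monotonicity(self, std_config):
        kds = np.linspace(0, 500, 101)
        states = [solve_equilibrium(std_config, kd) for kd in kds]
        total = std_config.l0 * (std_config.red_volume + std_config.white_volume)
        for s in states:
            recovered = (
                s.lwhite * std_config.white_volume + s.lred * std_config.red_volume
            )
            assert recovered == pytest.approx(total, rel=1e-9)
        pt = np.array([s.pt for s in states])
        lred = np.array([s.lred for s in states])
        lwhite = np.array([s.lwhite for s in states])
        assert np.all(np.diff(pt) < 0)
        assert np.all(np.diff(lred) < 0)
        assert np.all(np.diff(lwhite) > 0)


class TestInverseEstimators:
    @pytest.mark.parametrize(
        "l0, t0, pc, pt, expected",
        [
            (25, 80, 1.02, 1.21, 405),
            (25, 80, 1.02, 1.11, 882),
            (10, 40, 0.99, 1.21, 171),
        ],
    )
    def test_worked_determinations_from_pt(self, l0, t0, pc, pt, expected):
        config = ExperimentConfig(l0=l0, t0=t0, pc=pc)
        result = kd_from_pt(config, pt)
        assert round(result.kd) == expected
        assert result.method == "from_pt"

    def test_pt_at_control_ratio_is_no_binding(self, std_config):
        with pytest.raises(NoDetectableBindingError):
            kd_from_pt(std_config, std_config.pc)

    def test_pt_implying_excess_complex_is_infeasible(self):
        config = ExperimentConfig(l0=50, t0=1)
        with pytest.raises(InfeasibleMeasurementError):
            kd_from_pt(config, 2.0)

    @pytest.mark.parametrize(
        "lwhite, expected",
        [
            (40.0, 40.0),          # closed form reduces to w(w-30)/(50-w)
            (39.0, 351.0 / 11.0),
            (41.0, 451.0 / 9.0),
        ],
    )
    def test_kd_from_lwhite_exact_values(self, std_config, lwhite, expected):
        assert kd_from_lwhite(std_config, lwhite).kd == pytest.approx(expected, rel=1e-12)

    def test_lwhite_at_protein_free_level_is_no_binding(self, std_config):
        with pytest.raises(NoDetectableBindingError):
            kd_from_lwhite(std_config, 50.0)

    def test_lwhite_below_stoichiometric_floor_is_infeasible(self, std_config):
        # lwhite this low would require more complex than protein exists.
        with pytest.raises(InfeasibleMeasurementError):
            kd_from_lwhite(std_config, 20.0)

    @pytest.mark.parametrize("kd_true", [300.0, 500.0])
    def test_kd_from_lred_inverts_forward_solve(self, fig_config, kd_true):
        state = solve_equilibrium(fig_config, kd_true)
        assert kd_from_lred(fig_config, state.lred).kd == pytest.approx(kd_true, rel=1e-9)

    def test_lred_at_control_level_is_no_binding(self, fig_config):
        with pytest.raises(NoDetectableBindingError):
            kd_from_lred(fig_config, fig_config.l0)

    def test_flag_above_recommended_range(self, std_config):
        state = solve_equilibrium(std_config, 800.0)
        result = kd_from_lwhite(std_config, state.lwhite)
        assert result.reliability_flag == "above_recommended_range"
        assert result.kd == pytest.approx(800.0, rel=1e-8)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        l0=st.floats(1, 100),
        t0=st.floats(1, 200),
        redvol=st.floats(50, 500),
        whitevol=st.floats(50, 500),
        pc=st.floats(0.9, 1.1),
        log_kd=st.floats(-2, 4),
    )
    def test_round_trip_all_estimators(self, l0, t0, redvol, whitevol, pc, log_kd):
        """Each inverse estimator applied to its forward-solved observable
        recovers the generating K_D to 1e-8 relative."""
        config = ExperimentConfig(
            l0=l0, t0=t0, red_volume=redvol, white_volume=whitevol, pc=pc
        )
        kd = 10.0 ** log_kd
        state = solve_equilibrium(config, kd)
        assert kd_from_pt(config, state.pt).kd == pytest.approx(kd, rel=1e-8)
        assert kd_from_lwhite(config, state.lwhite).kd == pytest.approx(kd, rel=1e-8)
        assert kd_from_lred(config, state.lred).kd == pytest.approx(kd, rel=1e-8)

    def test_estimators_agree_on_consistent_observables(self, std_config):
        state = solve_equilibrium(std_config, 123.4)
        kds = [
            kd_from_pt(std_config, state.pt).kd,
            kd_from_lwhite(std_config, state.lwhite).kd,
            kd_from_lred(std_config, state.lred).kd,
        ]
        assert max(kds) == pytest.approx(min(kds), rel=1e-9)


class TestCheckPhysical:
    def test_valid_state_has_no_violations(self, std_config):
        state = solve_equilibrium(std_config, 75.0)
        assert check_physical(std_config, state, 75.0) == []

    def test_excess_complex_reported(self, std_config):
        import dataclasses

        state = solve_equilibrium(std_config, 75.0)
        bad = dataclasses.replace(state, tl=std_config.t0 + 10)
        assert "tf+tl=t0 violated" in check_physical(std_config, bad, 75.0)

    def test_perturbed_lwhite_breaks_conservation(self, std_config):
        import dataclasses

        state = solve_equilibrium(std_config, 75.0)
        bad = dataclasses.replace(state, lwhite=state.lwhite * 1.01)
        violations = check_physical(std_config, bad, 75.0)
        assert "ligand conservation violated" in violations
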