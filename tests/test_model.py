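"""Core ODE model: glucose input, steady state, adaptation, observation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from mignlme import (
    CellParameters,
    GlucoseProgram,
    ObservationModel,
    Trajectory,
    derive_k1,
    glucose_input,
    observe,
    simulate_cell,
    x_closed_form,
)
from mignlme import _kernels

GRID = np.arange(-30.0, 1201.0, 1.0)

rates = st.floats(min_value=1e-3, max_value=0.05)
glucose_levels = st.floats(min_value=0.1, max_value=4.0)


@pytest.mark.parametrize(
    "t, g, expected",
    [(-30.0, 1.5, 4.0), (300.0, 0.5, 0.5), (-1e-9, 1.0, 4.0), (0.0, 1.0, 1.0)],
)
def test_glucose_input_step(t, g, expected):
    """Pre-shift level before t=0; the shift applies at t=0 inclusive."""
    assert glucose_input(t, GlucoseProgram(post_level=g)) == expected


def test_glucose_input_no_step():
    prog = GlucoseProgram(post_level=4.0)
    t = np.linspace(-30, 1200, 7)
    assert np.all(glucose_input(t, prog) == 4.0)


@pytest.mark.parametrize(
    "k2, ms, glu0, expected",
    [(0.02, 3300.0, 4.0, 16.5), (0.00579, 3270.0, 4.0, 0.00579 * 3270.0 / 4.0)],
)
def test_derive_k1(k2, ms, glu0, expected):
    assert derive_k1(k2, ms, glu0) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad", [(0.02, 0.0, 4.0), (-0.1, 3300.0, 4.0), (0.02, 3300.0, 0.0)])
def test_derive_k1_requires_positive_inputs(bad):
    with pytest.raises(ValueError):
        derive_k1(*bad)


def test_program_invariants():
    with pytest.raises(ValueError):
        GlucoseProgram(post_level=-1.0)
    with pytest.raises(ValueError):
        GlucoseProgram(post_level=1.0, start_time=10.0)


@given(k4=rates, g=glucose_levels, t=st.floats(min_value=0.0, max_value=2000.0))
def test_x_closed_form_matches_formula(k4, g, t):
    """X(t) = g/4 + (1 - g/4) exp(-k4 t) after the shift, to 1e-8 relative."""
    prog = GlucoseProgram(post_level=g)
    expected = g / 4.0 + (1.0 - g / 4.0) * np.exp(-k4 * t)
    assert x_closed_form(t, k4, prog) == pytest.approx(expected, rel=1e-8)


def test_x_closed_form_value():
    assert x_closed_form(600.0, 0.005, GlucoseProgram(post_level=1.0)) == pytest.approx(
        0.25 + 0.75 * np.exp(-3.0), rel=1e-12
    )


def test_no_shift_stays_at_steady_state():
    traj = simulate_cell(CellParameters(3300.0, 0.02, 0.005),
                         GlucoseProgram(post_level=4.0), GRID)
    assert np.all(traj.mig1 == 3300.0)
    assert np.all(traj.x == 1.0)


def test_pre_shift_values_are_exact():
    traj = simulate_cell(CellParameters(3640.0, 0.00592, 0.00999),
                         GlucoseProgram(post_level=1.0), GRID)
    pre = traj.times <= 0
    assert np.all(traj.mig1[pre] == 3640.0)
    assert np.all(traj.x[pre] == 1.0)


@given(k2=rates, k4=rates, g=st.floats(min_value=0.25, max_value=3.5))
def test_perfect_adaptation(k2, k4, g):
    """Mig1 returns to within 0.1% of M_s once both relaxation modes decay.

    The late-time Mig1 relaxation rate is k2*X(inf) = k2*g/4 (not k2
    itself), so the horizon uses the slower of that and the adaptation
    rate k4.
    """
    ms = 3000.0
    horizon = 20.0 / min(k2 * g / 4.0, k4)
    grid = np.array([-30.0, 0.0, horizon])
    traj = simulate_cell(CellParameters(ms, k2, k4), GlucoseProgram(post_level=g), grid)
    assert abs(traj.mig1[-1] - ms) / ms < 1e-3


@given(k2=rates, k4=rates, c=st.floats(min_value=0.1, max_value=10.0))
def test_scale_equivariance_in_baseline(k2, k4, c):
    """Scaling M_s scales Mig1(t) pointwise and leaves X(t) unchanged."""
    prog = GlucoseProgram(post_level=1.0)
    grid = np.arange(-30.0, 601.0, 10.0)
    a = simulate_cell(CellParameters(2000.0, k2, k4), prog, grid)
    b = simulate_cell(CellParameters(2000.0 * c, k2, k4), prog, grid)
    np.testing.assert_allclose(b.mig1, c * a.mig1, rtol=1e-9)
    np.testing.assert_allclose(b.x, a.x, rtol=0, atol=0)


def test_reduction_equivalence_with_four_parameter_model():
    """The unreduced model with k3 = k4/Glu(-30), X_s = 1 gives identical Mig1.

    Integrates the pre-reduction system (independent oracle, both state
    variables as ODEs) at tight tolerance and compares with the reduced
    closed-form-X route.
    """
    ms, k2, k4 = 3300.0, 0.00579, 0.00846
    g, glu0 = 1.5, 4.0
    k1 = k2 * ms / glu0
    k3 = k4 / glu0

    def rhs(t, y):
        mig1, x = y
        return [k1 * g - k2 * x * mig1, k3 * g - k4 * x]

    t_eval = np.arange(0.0, 1201.0, 1.0)
    sol = solve_ivp(rhs, (0.0, 1200.0), [ms, 1.0], t_eval=t_eval,
                    rtol=1e-12, atol=1e-12, method="DOP853")
    grid = np.concatenate([[-30.0], t_eval])
    reduced = simulate_cell(CellParameters(ms, k2, k4), GlucoseProgram(post_level=g),
                            grid, rtol=1e-11, atol=1e-11)
    np.testing.assert_allclose(reduced.mig1[1:], sol.y[0], rtol=1e-8)
    np.testing.assert_allclose(reduced.x[1:], sol.y[1], rtol=1e-8)


def test_fast_kernel_agrees_with_adaptive_integrator():
    """Compiled fixed-step route vs scipy adaptive route (independent paths)."""
    prog = GlucoseProgram(post_level=1.0)
    p = CellParameters(3640.0, 0.00592, 0.00999)
    traj = simulate_cell(p, prog, GRID, rtol=1e-12, atol=1e-13)
    pred = _kernels.mig1_pred(GRID, p.M_s, p.k2, p.k4, prog.ratio)
    np.testing.assert_allclose(pred, traj.mig1, rtol=0, atol=1e-8 * p.M_s)


class TestObserve:
    prog = GlucoseProgram(post_level=1.0)
    traj = simulate_cell(CellParameters(3300.0, 0.02, 0.005), prog, GRID)

    def test_zero_noise_is_exact(self):
        t = np.array([-30.0, 0.0, 60.0, 600.0])
        y = observe(self.traj, ObservationModel(0.0), t, seed=0)
        np.testing.assert_array_equal(y, self.traj.mig1_at(t))

    def test_background_is_additive(self):
        t = np.array([0.0, 120.0])
        y = observe(self.traj, ObservationModel(0.0, background=500.0), t, seed=0)
        np.testing.assert_array_equal(y, self.traj.mig1_at(t) + 500.0)

    def test_noise_variance_law_of_large_numbers(self):
        y = observe(self.traj, ObservationModel(40_000.0), np.full(100_000, 300.0),
                    seed=123)
        assert np.var(y) == pytest.approx(40_000.0, rel=0.02)

    def test_reproducible_given_seed(self):
        t = np.arange(0.0, 1200.0, 100.0)
        a = observe(self.traj, ObservationModel(1000.0), t, seed=7)
        b = observe(self.traj, ObservationModel(1000.0), t, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_times_outside_span_error(self):
        with pytest.raises(ValueError):
            observe(self.traj, ObservationModel(0.0), np.array([5000.0]), seed=0)


def test_trajectory_validation_and_csv_roundtrip(tmp_path):
    t = np.array([0.0, 1.0, 2.0])
    traj = Trajectory(t, np.array([3.0, 2.0, 2.5]), np.array([1.0, 0.9, 0.8]))
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    back = Trajectory.from_csv(path)
    np.testing.assert_allclose(back.mig1, traj.mig1)
    with pytest.raises(ValueError):
        Trajectory(t[::-1], traj.mig1, traj.x)
    with pytest.raises(ValueError):
        Trajectory(t, traj.mig1[:2], traj.x)
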