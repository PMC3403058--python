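"""Integrators and oscillation summaries."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from cyclesync import (NoiseSpec, SignalSpec, Trajectory,
                       integrate_deterministic, integrate_stochastic,
                       single_cell_rhs, summarize_oscillation,
                       draw_initial_conditions)
from cyclesync.simulate import InsufficientDataError


def test_single_cell_limit_cycle_period(single_traj):
    summ = summarize_oscillation(single_traj)
    assert summ.attractor == "oscillatory"
    assert summ.period == pytest.approx(3.78, rel=0.02)


def test_coupled_limit_cycle_period(coupled_traj):
    summ = summarize_oscillation(coupled_traj)
    assert summ.attractor == "oscillatory"
    assert summ.period == pytest.approx(4.315, rel=0.02)


def test_equilibrium_stays_constant(params):
    # fixed point of the single-cell RHS found by root-solving
    root = fsolve(lambda y: single_cell_rhs(y, 0.0, params, 0.1),
                  [0.1, 0.3, 0.2], full_output=False)
    resid = np.abs(single_cell_rhs(root, 0.0, params, 0.1)).max()
    assert resid < 1e-10
    traj = integrate_deterministic(params, None, 0.1, root, 20.0,
                                   dt_out=0.01)
    assert np.abs(traj.states - root).max() < 1e-6


def test_forward_invariance_of_state_box(coupled_traj):
    N = coupled_traj.N
    S = coupled_traj.states
    assert S[:, :N].min() >= -1e-9            # C >= 0
    assert S[:, 3 * N].min() >= -1e-9         # R >= 0
    assert S[:, N:3 * N].min() >= -1e-9       # P, A >= 0
    assert S[:, N:3 * N].max() <= 1 + 1e-9    # P, A <= 1


def test_tolerance_refinement_stability(params):
    x0 = np.random.default_rng(5).uniform(0, 1, 3)
    periods = []
    for rtol, atol in [(1e-8, 1e-10), (5e-9, 5e-11)]:
        traj = integrate_deterministic(params, None, 0.1, x0, 120.0,
                                       dt_out=0.002, rtol=rtol, atol=atol)
        periods.append(summarize_oscillation(traj).period)
    assert abs(periods[0] - periods[1]) / periods[0] < 1e-3


def test_summary_on_known_waveform():
    t = np.arange(0, 100, 0.01)
    x = 0.5 + 0.3 * np.sin(2 * np.pi * t / 5)
    traj = Trajectory(times=t, states=np.column_stack([x, x, x]))
    summ = summarize_oscillation(traj)
    assert summ.attractor == "oscillatory"
    assert summ.period == pytest.approx(5.0, abs=0.01)
    assert summ.amplitude == pytest.approx(0.6, abs=0.01)


def test_summary_constant_is_steady():
    t = np.arange(0, 50, 0.01)
    x = np.full_like(t, 0.7)
    traj = Trajectory(times=t, states=np.column_stack([x, x, x]))
    assert summarize_oscillation(traj).attractor == "steady"


def test_summary_invariant_to_prepended_transient(params):
    x0 = np.random.default_rng(2).uniform(0, 1, 3)
    traj = integrate_deterministic(params, None, 0.1, x0, 120.0,
                                   dt_out=0.002)
    settled = integrate_deterministic(params, None, 0.1,
                                      traj.final_state(), 120.0,
                                      dt_out=0.002)
    padded = Trajectory(
        times=np.concatenate([traj.times, settled.times + 120.0]),
        states=np.vstack([traj.states, settled.states]))
    a = summarize_oscillation(settled)
    b = summarize_oscillation(padded)
    assert a.attractor == b.attractor == "oscillatory"
    assert a.period == pytest.approx(b.period, rel=1e-3)


def test_summary_rejects_tiny_trajectory():
    traj = Trajectory(times=np.arange(5.0),
                      states=np.zeros((5, 3)))
    with pytest.raises(InsufficientDataError):
        summarize_oscillation(traj)


def test_stochastic_zero_noise_matches_euler(params, coupling):
    x0 = draw_initial_conditions(coupling, 7)
    traj = integrate_stochastic(params, coupling, 0.1, x0, 2.0, dt=1e-3,
                                noise=NoiseSpec(intensity=0.0),
                                dt_out=0.1)
    # hand-rolled Euler for the same step
    from cyclesync import coupled_rhs
    y = x0.copy()
    for i in range(2000):
        y = y + coupled_rhs(y, i * 1e-3, params, coupling, 0.1) * 1e-3
        y = np.clip(y, 0,
                    np.concatenate([np.full(10, np.inf), np.ones(20),
                                    [np.inf]]))
    np.testing.assert_allclose(traj.states[-1], y, rtol=1e-10)


def test_stochastic_reproducible_and_noise_dependent(params, coupling):
    x0 = draw_initial_conditions(coupling, 8)
    kw = dict(dt=1e-3, noise=NoiseSpec(intensity=0.001, seed=3),
              dt_out=0.1)
    a = integrate_stochastic(params, coupling, 0.1, x0, 2.0, **kw)
    b = integrate_stochastic(params, coupling, 0.1, x0, 2.0, **kw)
    np.testing.assert_array_equal(a.states, b.states)
    c = integrate_stochastic(params, coupling, 0.1, x0, 2.0, dt=1e-3,
                             noise=NoiseSpec(intensity=0.001, seed=4),
                             dt_out=0.1)
    assert not np.array_equal(a.states, c.states)


def test_stochastic_converges_to_deterministic_path(params, coupling):
    """Ensemble mean at small intensity tracks the deterministic path."""
    x0 = draw_initial_conditions(coupling, 11)
    det = integrate_deterministic(params, coupling, 0.1, x0, 5.0,
                                  dt_out=0.5)
    finals = []
    for s in range(20):
        sto = integrate_stochastic(params, coupling, 0.1, x0, 5.0,
                                   dt=5e-4,
                                   noise=NoiseSpec(intensity=0.001,
                                                   seed=s),
                                   dt_out=0.5)
        finals.append(sto.states[-1])
    finals = np.array(finals)
    mean = finals.mean(axis=0)
    sem = finals.std(axis=0, ddof=1) / np.sqrt(len(finals))
    # within 3 standard errors plus the Euler discretization bias
    assert np.all(np.abs(mean - det.states[-1]) < 3 * sem + 5e-3)


def test_square_wave_integration_matches_fine_reference(params, coupling):
    """Piecewise restarts at square edges agree with a brute-force path."""
    sig = SignalSpec(kind="square", aq=0.6)
    x0 = draw_initial_conditions(coupling, 1)
    traj = integrate_deterministic(params, coupling, sig, x0, 5.0,
                                   dt_out=0.1)
    ref = integrate_stochastic(params, coupling, sig, x0, 5.0, dt=2e-5,
                               noise=NoiseSpec(intensity=0.0), dt_out=0.1)
    np.testing.assert_allclose(traj.states[-1], ref.states[-1],
                               atol=2e-4)
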