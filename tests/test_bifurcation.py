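"""Brute-force sweeps: attractor classes, bistability, pulse switching."""

import numpy as np
import pytest

from cyclesync import (SignalSpec, classify_region_2d, detect_hysteresis,
                       draw_initial_conditions, integrate_deterministic,
                       integrate_stochastic, pulse_response,
                       summarize_oscillation, sweep_1d)
from cyclesync.simulate import NoiseSpec


def test_table1_point_is_oscillatory(params, coupling):
    res = sweep_1d("k", [1.0], params, coupling, mode="independent",
                   n_ic=3, t_end=150.0, seed=1)
    assert res.classification[0] == "oscillatory"


def test_monostable_window_has_identical_branches(params, coupling):
    """Far above the bistable window both sweep directions agree."""
    grid = np.linspace(2.4, 2.8, 5)
    fwd = sweep_1d("k", grid, params, coupling, mode="continuation",
                   t_end=100.0, dt_out=0.02, seed=0)
    bwd = sweep_1d("k", grid[::-1], params, coupling, mode="continuation",
                   t_end=100.0, dt_out=0.02, seed=0)
    assert bwd.direction == "backward"
    assert not detect_hysteresis(fwd, bwd).any()


def test_hysteresis_in_coupling_strength_window(params, coupling):
    """Forward and backward k-continuation disagree inside the
    bistable window between the oscillatory and high-CDK1 regimes."""
    grid = np.linspace(1.3, 1.7, 9)
    fwd = sweep_1d("k", grid, params, coupling, mode="continuation",
                   t_end=120.0, dt_out=0.02, seed=0)
    bwd = sweep_1d("k", grid[::-1], params, coupling, mode="continuation",
                   t_end=120.0, dt_out=0.02, seed=0)
    mask = detect_hysteresis(fwd, bwd)
    assert mask.any()
    # branch extrema are continuous away from the detected transition
    jumps = np.abs(np.diff(fwd.cmax))
    assert np.sort(jumps)[:-2].max() < 0.1


def test_regime_switch_with_plk1_activation_rate(params, coupling):
    """Lowering the Plk1 activation rate at intermediate K2 turns the
    synchronized oscillation into a steady state."""
    region = classify_region_2d("K2", "alpha2", [0.35, 0.42], [1.0, 1.6],
                                params, coupling, n_ic=2, t_end=150.0,
                                seed=3)
    assert set(region.classification[0]) == {"steady"}        # alpha2=1.0
    assert set(region.classification[1]) == {"oscillatory"}   # alpha2=1.6
    assert region.classification.shape == (2, 2)


def test_noise_driven_regime_switch(params, coupling):
    """With intrinsic noise of intensity 0.001, stepping the Plk1
    activation rate from 0.9 to 1.7 takes the system from a quiet steady
    state to full oscillation (K2 between the two synchronization
    intervals)."""
    p = params.replace(K2=0.3, alpha2=0.9)
    x0 = draw_initial_conditions(coupling, 5)
    quiet = integrate_stochastic(p, coupling, 0.1, x0, 80.0, dt=1e-3,
                                 noise=NoiseSpec(0.001, 1), dt_out=0.01)
    span_quiet = np.ptp(quiet.observable("C", 0)[-3000:])
    p2 = p.replace(alpha2=1.7)
    loud = integrate_stochastic(p2, coupling, 0.1, quiet.final_state(),
                                80.0, dt=1e-3, noise=NoiseSpec(0.001, 2),
                                dt_out=0.01)
    span_loud = np.ptp(loud.observable("C", 0)[-3000:])
    assert span_quiet < 0.02
    assert span_loud > 0.1


def test_pulse_response_verdicts(params, coupling):
    c = coupling.replace(k=1.6)
    x0 = np.concatenate([np.full(30, 0.1), [0.0]])
    settle = integrate_deterministic(params, c, 0.1, x0, 100.0, dt_out=0.1)
    start = settle.final_state()
    # zero-amplitude pulse leaves the attractor untouched
    _, verdict = pulse_response(params, c, SignalSpec(kind="square",
                                                      aq=0.0),
                                start)
    assert verdict == "unchanged"
    # a real pulse drives CDK1 upward from its resting level
    traj, verdict = pulse_response(params, c, SignalSpec(kind="square",
                                                         aq=0.6), start)
    assert verdict in {"switched-up", "switched-and-stuck", "oscillates"}
    assert traj.observable("C", 0).max() > start[0] + 0.05


def test_unknown_parameter_rejected(params, coupling):
    with pytest.raises(KeyError):
        sweep_1d("gamma", [0.1, 0.2], params, coupling)


def test_sustained_square_wave_drives_oscillation_at_high_k(params,
                                                            coupling):
    """At k = 1.6 (steady regime under constant input) a sustained
    square-wave cyclin-synthesis input keeps CDK1 oscillating."""
    c = coupling.replace(k=1.6)
    sig = SignalSpec(kind="square", aq=0.6)
    x0 = np.concatenate([np.full(30, 0.1), [0.0]])
    steady = integrate_deterministic(params, c, 0.1, x0, 150.0,
                                     dt_out=0.01)
    assert summarize_oscillation(steady).attractor == "steady"
    driven = integrate_deterministic(params, c, sig, x0, 150.0,
                                     dt_out=0.01)
    assert summarize_oscillation(driven).attractor == "oscillatory"
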