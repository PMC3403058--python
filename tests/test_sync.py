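"""Synchronization error, synchronization time, and the sync manifold."""

import numpy as np
import pytest

from cyclesync import (SystemState, draw_initial_conditions,
                       integrate_deterministic, sync_error,
                       sync_error_series, sync_time, synchronized_at_end)
from cyclesync.model import pack_state
from cyclesync.simulate import InsufficientDataError, Trajectory


def _state(C, P, A, R=0.0):
    return SystemState(C=np.asarray(C, float), P=np.asarray(P, float),
                       A=np.asarray(A, float), R=R)


def test_sync_error_zero_for_identical_cells():
    s = _state([0.3] * 5, [0.6] * 5, [0.1] * 5)
    assert sync_error(s) == 0.0


def test_sync_error_direct_values():
    # N=2, only C differs by 1: E = 1/2
    s = _state([0.0, 1.0], [0.5, 0.5], [0.5, 0.5])
    assert sync_error(s) == pytest.approx(0.5)
    # N=3, C=(0,1,2): E = (1+4)/3
    s = _state([0.0, 1.0, 2.0], [0.2] * 3, [0.9] * 3)
    assert sync_error(s) == pytest.approx(5.0 / 3.0)


def test_sync_error_flat_vector_form():
    y = pack_state([0.0, 1.0], [0.5, 0.5], [0.5, 0.5], 0.3)
    assert sync_error(y, N=2) == pytest.approx(0.5)


def test_sync_error_invariant_to_permuting_nonreference_cells():
    rng = np.random.default_rng(0)
    C, P, A = rng.uniform(0, 1, (3, 8))
    e0 = sync_error(_state(C, P, A))
    perm = np.concatenate([[0], 1 + rng.permutation(7)])
    e1 = sync_error(_state(C[perm], P[perm], A[perm]))
    assert e1 == pytest.approx(e0, rel=1e-12)


def test_sync_error_requires_two_cells():
    with pytest.raises(ValueError):
        sync_error(_state([0.1], [0.1], [0.1]))


def test_synchronous_manifold_is_invariant(params, coupling):
    """Identical initial conditions keep E at integrator noise level."""
    x0 = draw_initial_conditions(coupling, 3, spread=0.0)
    traj = integrate_deterministic(params, coupling, 0.1, x0, 50.0,
                                   dt_out=0.05)
    E = sync_error_series(traj)
    assert E.max() < 1e-10
    res = sync_time(traj)
    assert res.synchronized and res.sync_time == 0.0


def test_sync_time_on_table1_system(coupled_traj):
    res = sync_time(coupled_traj)
    assert res.synchronized
    assert 0 < res.sync_time < 100
    # after the declared time the error stays below threshold
    after = res.times >= res.sync_time
    assert (res.error_series[after] < res.threshold).all()
    assert synchronized_at_end(coupled_traj)


def test_sync_time_hold_rejects_transient_dips():
    # crafted error series: brief dip below threshold, then resurgence
    t = np.arange(0, 100, 0.1)
    E = np.full_like(t, 1e-3)
    E[(t >= 20) & (t < 25)] = 1e-7     # 5-min dip, shorter than hold
    E[t >= 60] = 1e-8                  # permanent synchronization
    N = 2
    states = np.zeros((len(t), 7))
    states[:, 1] = np.sqrt(2 * E)      # C2-C1 encodes E for N=2
    traj = Trajectory(times=t, states=states)
    res = sync_time(traj, threshold=1e-5, hold=20.0)
    assert res.synchronized
    assert res.sync_time == pytest.approx(60.0, abs=0.2)


def test_out_of_interval_parameters_do_not_synchronize(params, coupling):
    """K1 = 0.3 sits outside the synchronization range of K1."""
    p = params.replace(K1=0.3)
    x0 = draw_initial_conditions(coupling, 9)
    traj = integrate_deterministic(p, coupling, 0.1, x0, 200.0,
                                   dt_out=0.05)
    assert not synchronized_at_end(traj)


def test_sync_time_insufficient_span(coupled_traj):
    short = Trajectory(times=coupled_traj.times[:100],
                       states=coupled_traj.states[:100])
    with pytest.raises(InsufficientDataError):
        sync_time(short, hold=20.0)


def test_sync_time_decreases_with_coupling_strength(params, coupling):
    """Stronger coupling pulls scattered cells together faster."""
    times = []
    for k in (1.0, 1.3):
        c = coupling.replace(k=k)
        x0 = draw_initial_conditions(c, 21)
        traj = integrate_deterministic(params, c, 0.1, x0, 150.0,
                                       dt_out=0.05)
        res = sync_time(traj)
        assert res.synchronized
        times.append(res.sync_time)
    assert times[1] < times[0]
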