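"""Synchronization error, synchronization time, and interval scans.

The synchronization error of an N-cell state takes cell 1 as reference:

    E = (1/N) * sum_{i=2..N} [(C_i-C_1)^2 + (P_i-P_1)^2 + (A_i-A_1)^2]

The coupled system is declared synchronized when E < 1e-5.  Two protocols
are distinguished:

* attainment — the first time E falls below the threshold and stays there
  for a hold window (`sync_time`);
* persistence — E is below the threshold throughout the final hold window
  of a finite horizon (`synchronized_at_end`), used by interval scans.

The distinction matters because part of the parameter space supports only
marginally stable synchrony: cells started nearly synchronized drift apart
so slowly that synchrony persists over hundreds of minutes without being
asymptotically stable.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .params import CouplingParams, ParameterSet
from .simulate import (InsufficientDataError, Trajectory,
                       draw_initial_conditions, integrate_deterministic,
                       summarize_oscillation)

__all__ = [
    "SyncResult", "IntervalScan",
    "sync_error", "sync_error_series", "sync_time", "synchronized_at_end",
    "scan_sync_interval", "set_parameter",
]

SYNC_THRESHOLD = 1e-5
DEFAULT_HOLD = 20.0  # min, roughly five periods of the nominal oscillation


@dataclass
class SyncResult:
    """Outcome of a synchronization-time measurement along one trajectory."""

    times: np.ndarray
    error_series: np.ndarray
    synchronized: bool
    sync_time: float | None
    threshold: float


@dataclass
class IntervalScan:
    """Synchronization verdicts over a 1-D parameter grid.

    ``synchronized_mask`` marks grid points where every IC replicate kept
    E below threshold through the final hold window *and* the reference
    cell oscillates.  ``amplitude_death_mask`` marks points synchronized to
    a steady (non-oscillatory) state.  ``intervals`` are the maximal runs
    of synchronized points as (lo, hi) grid values.
    """

    parameter: str
    grid: np.ndarray
    synchronized_mask: np.ndarray
    amplitude_death_mask: np.ndarray
    intervals: list[tuple[float, float]]
    period: np.ndarray
    amplitude: np.ndarray


def sync_error(state, N: int | None = None) -> float:
    """Synchronization error E of one state (flat vector or SystemState)."""
    if hasattr(state, "C"):
        C, P, A = state.C, state.P, state.A
        N = len(C)
    else:
        y = np.asarray(state, dtype=float)
        if N is None:
            raise ValueError("N is required for flat state vectors")
        C, P, A = y[:N], y[N:2 * N], y[2 * N:3 * N]
    if N < 2:
        raise ValueError("synchronization error needs N >= 2 cells")
    return float(((C[1:] - C[0]) ** 2 + (P[1:] - P[0]) ** 2
                  + (A[1:] - A[0]) ** 2).sum() / N)


def sync_error_series(traj: Trajectory) -> np.ndarray:
    """E(t) along a coupled trajectory."""
    N = traj.N
    if N < 2:
        raise ValueError("synchronization error needs N >= 2 cells")
    S = traj.states
    C, P, A = S[:, :N], S[:, N:2 * N], S[:, 2 * N:3 * N]
    return (((C[:, 1:] - C[:, :1]) ** 2 + (P[:, 1:] - P[:, :1]) ** 2
             + (A[:, 1:] - A[:, :1]) ** 2).sum(axis=1) / N)


def _hold_steps(times: np.ndarray, hold: float) -> int:
    dt = times[1] - times[0]
    return max(1, int(round(hold / dt)))


def sync_time(traj: Trajectory, threshold: float = SYNC_THRESHOLD,
              hold: float = DEFAULT_HOLD) -> SyncResult:
    """First time E drops below ``threshold`` and stays there for ``hold``.

    Returns ``synchronized=False`` when no such time exists before the end
    of the trajectory (the hold window must fit before t_end).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    E = sync_error_series(traj)
    t = traj.times
    if t[-1] - t[0] < hold:
        raise InsufficientDataError(
            f"trajectory span {t[-1] - t[0]:g} min is shorter than the "
            f"hold window {hold:g} min")
    w = _hold_steps(t, hold)
    below = E < threshold
    n = len(below)
    # run[i] = number of consecutive below-threshold samples starting at i
    nxt_false = np.minimum.accumulate(
        np.where(~below, np.arange(n), n)[::-1])[::-1]
    run = nxt_false - np.arange(n)
    ok = np.nonzero(run >= w + 1)[0]
    if ok.size:
        return SyncResult(times=t, error_series=E, synchronized=True,
                          sync_time=float(t[ok[0]]), threshold=threshold)
    return SyncResult(times=t, error_series=E, synchronized=False,
                      sync_time=None, threshold=threshold)


def synchronized_at_end(traj: Trajectory, threshold: float = SYNC_THRESHOLD,
                        hold: float = DEFAULT_HOLD) -> bool:
    """True when E stays below ``threshold`` through the final hold window."""
    E = sync_error_series(traj)
    w = _hold_steps(traj.times, hold)
    return bool((E[-w:] < threshold).all())


_PARAM_FIELDS = {f.name for f in fields(ParameterSet)}
_COUPLING_FIELDS = {f.name for f in fields(CouplingParams)}


def set_parameter(params: ParameterSet, coupling: CouplingParams,
                  name: str, value) -> tuple[ParameterSet, CouplingParams]:
    """Return copies of (params, coupling) with one named field replaced."""
    if name in _PARAM_FIELDS:
        return params.replace(**{name: value}), coupling
    if name in _COUPLING_FIELDS:
        return params, coupling.replace(**{name: value})
    raise KeyError(f"unknown parameter {name!r}")


def scan_sync_interval(parameter: str, grid, params: ParameterSet,
                       coupling: CouplingParams, signal=None,
                       n_ic: int = 5, t_end: float = 500.0,
                       dt_out: float = 0.02,
                       ic_spread: float | None = 0.002,
                       threshold: float = SYNC_THRESHOLD,
                       hold: float = DEFAULT_HOLD,
                       seed: int = 0) -> IntervalScan:
    """Locate synchronization intervals of one parameter.

    For each grid value the coupled system is integrated from ``n_ic``
    seeded initial conditions.  A grid point counts as synchronized when
    *every* replicate keeps E below ``threshold`` through the final hold
    window and the reference cell oscillates; synchronized-but-steady
    points are flagged as amplitude death instead.

    ``ic_spread`` controls the replicate initial conditions: ``None`` draws
    each cell independently from the unit box (attainment of synchrony from
    scattered phases), while a small value starts the cells nearly
    synchronized and asks whether synchrony *persists* over the horizon.
    The default probes persistence, which is the only protocol that exposes
    the weakly stable low-K2 synchronization window.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    base_alpha1 = signal if signal is not None else params.alpha1
    n_pts = len(grid)
    sync_mask = np.zeros(n_pts, dtype=bool)
    death_mask = np.zeros(n_pts, dtype=bool)
    period = np.full(n_pts, np.nan)
    amplitude = np.full(n_pts, np.nan)
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_pts * n_ic).reshape(n_pts, n_ic)
    for j, value in enumerate(grid):
        p, c = set_parameter(params, coupling, parameter, value)
        all_sync = True
        all_osc = True
        periods, amps = [], []
        for r in range(n_ic):
            x0 = draw_initial_conditions(c, int(rep_seeds[j, r]) % (2 ** 31),
                                         spread=ic_spread)
            traj = integrate_deterministic(p, c, base_alpha1, x0, t_end,
                                           dt_out=dt_out)
            if not synchronized_at_end(traj, threshold, hold):
                all_sync = False
                break
            summ = summarize_oscillation(traj)
            if summ.attractor == "oscillatory":
                periods.append(summ.period)
                amps.append(summ.amplitude)
            else:
                all_osc = False
        if all_sync and all_osc and periods:
            sync_mask[j] = True
            period[j] = np.mean(periods)
            amplitude[j] = np.mean(amps)
        elif all_sync:
            death_mask[j] = True
    intervals = []
    in_run = False
    lo = None
    for j, s in enumerate(sync_mask):
        if s and not in_run:
            in_run, lo = True, grid[j]
        elif not s and in_run:
            intervals.append((float(lo), float(grid[j - 1])))
            in_run = False
    if in_run:
        intervals.append((float(lo), float(grid[-1])))
    return IntervalScan(parameter=parameter, grid=grid,
                        synchronized_mask=sync_mask,
                        amplitude_death_mask=death_mask,
                        intervals=intervals, period=period,
                        amplitude=amplitude)
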