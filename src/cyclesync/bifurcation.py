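"""Brute-force bifurcation classification, bistability and hysteresis.

Instead of numerical continuation, attractors are classified by dense
parameter sweeps: at each grid point the system is integrated to its
attractor and the late-time behavior of C_1 is classified as steady or
oscillatory.  Two initial-condition policies are available:

* independent — several random initial conditions per point; disagreement
  between replicates (different attractor classes, or steady levels that
  differ) flags bistability;
* continuation — the grid is traversed in order and each point starts from
  the previous point's final state, so a forward/backward pair of sweeps
  traces hysteresis branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CouplingParams, ParameterSet
from .signals import SignalSpec
from .simulate import (Trajectory, draw_initial_conditions,
                       integrate_deterministic, summarize_oscillation)
from .sync import set_parameter

__all__ = ["SweepResult", "Region2D", "sweep_1d", "detect_hysteresis",
           "classify_region_2d", "pulse_response"]

# steady levels further apart than this are treated as distinct branches
BRANCH_TOL = 0.05


@dataclass
class SweepResult:
    """Per-point classification along a 1-D parameter sweep.

    ``classification`` entries are "steady", "oscillatory", "bistable" or
    "undetermined".  ``cmin``/``cmax`` are the attractor extrema of C_1
    (for independent mode, of the first replicate).
    """

    parameter: str
    grid: np.ndarray
    classification: np.ndarray
    cmin: np.ndarray
    cmax: np.ndarray
    mode: str
    direction: str = "forward"


@dataclass
class Region2D:
    """Classification over a 2-D parameter grid (rows = y, cols = x)."""

    param_x: str
    param_y: str
    grid_x: np.ndarray
    grid_y: np.ndarray
    classification: np.ndarray


def _attractor_of(traj: Trajectory, tail_fraction: float = 0.25):
    """Late-time class and C_1 extrema of one trajectory."""
    summ = summarize_oscillation(traj)
    t = traj.times
    c = traj.observable("C", 0)
    tail = c[t >= t[0] + (1 - tail_fraction) * (t[-1] - t[0])]
    return summ.attractor, float(tail.min()), float(tail.max())


def sweep_1d(parameter: str, grid, params: ParameterSet,
             coupling: CouplingParams, signal=None,
             mode: str = "independent", n_ic: int = 5,
             t_end: float = 150.0, dt_out: float = 0.01,
             seed: int = 0, x0=None) -> SweepResult:
    """Classify attractors along a 1-D parameter grid.

    ``mode="independent"`` integrates ``n_ic`` random initial conditions
    per point; a point is bistable when replicates disagree (class or
    steady level).  ``mode="continuation"`` follows the attractor branch:
    each point starts from the previous final state (pass a decreasing
    grid, or reverse it, for the backward branch).
    """
    grid = np.asarray(grid, dtype=float)
    sig = signal if signal is not None else params.alpha1
    n_pts = len(grid)
    classification = np.empty(n_pts, dtype=object)
    cmin = np.empty(n_pts)
    cmax = np.empty(n_pts)
    ss = np.random.SeedSequence(seed)
    if mode == "independent":
        rep_seeds = ss.generate_state(n_pts * n_ic).reshape(n_pts, n_ic)
        for j, value in enumerate(grid):
            p, c = set_parameter(params, coupling, parameter, value)
            classes, lows, highs = [], [], []
            for r in range(n_ic):
                ic = draw_initial_conditions(
                    c, int(rep_seeds[j, r]) % (2 ** 31))
                traj = integrate_deterministic(p, c, sig, ic, t_end,
                                               dt_out=dt_out)
                kind, lo, hi = _attractor_of(traj)
                classes.append(kind)
                lows.append(lo)
                highs.append(hi)
            cmin[j], cmax[j] = lows[0], highs[0]
            kinds = set(classes)
            if kinds == {"steady"}:
                # distinct steady levels across replicates => bistable
                if max(lows) - min(lows) > BRANCH_TOL:
                    classification[j] = "bistable"
                else:
                    classification[j] = "steady"
            elif kinds == {"oscillatory"}:
                classification[j] = "oscillatory"
            elif kinds <= {"steady", "oscillatory"}:
                classification[j] = "bistable"
            else:
                classification[j] = "undetermined"
    elif mode == "continuation":
        direction = "forward" if n_pts < 2 or grid[1] > grid[0] \
            else "backward"
        if x0 is None:
            x0 = draw_initial_conditions(coupling,
                                         int(ss.generate_state(1)[0])
                                         % (2 ** 31))
        y = np.asarray(x0, dtype=float)
        for j, value in enumerate(grid):
            p, c = set_parameter(params, coupling, parameter, value)
            traj = integrate_deterministic(p, c, sig, y, t_end,
                                           dt_out=dt_out)
            classification[j], cmin[j], cmax[j] = _attractor_of(traj)
            y = traj.final_state()
        order = np.argsort(grid)
        return SweepResult(parameter=parameter, grid=grid[order],
                           classification=classification[order],
                           cmin=cmin[order], cmax=cmax[order],
                           mode=mode, direction=direction)
    else:
        raise ValueError(f"unknown sweep mode {mode!r}")
    return SweepResult(parameter=parameter, grid=grid,
                       classification=classification,
                       cmin=cmin, cmax=cmax, mode=mode)


def detect_hysteresis(forward: SweepResult, backward: SweepResult,
                      tol: float = BRANCH_TOL) -> np.ndarray:
    """Boolean mask of grid points where the two branches disagree.

    Both sweeps must share the same (ascending) grid.  Disagreement means
    the attractor extrema of C_1 differ by more than ``tol`` — the
    signature of coexisting attractors selected by history.
    """
    if not np.allclose(forward.grid, backward.grid):
        raise ValueError("sweeps were run on different grids")
    return (np.abs(forward.cmin - backward.cmin) > tol) \
        | (np.abs(forward.cmax - backward.cmax) > tol)


def classify_region_2d(param_x: str, param_y: str, grid_x, grid_y,
                       params: ParameterSet, coupling: CouplingParams,
                       signal=None, n_ic: int = 3, t_end: float = 150.0,
                       dt_out: float = 0.01, seed: int = 0) -> Region2D:
    """Attractor class over a Cartesian 2-D parameter grid."""
    grid_x = np.asarray(grid_x, dtype=float)
    grid_y = np.asarray(grid_y, dtype=float)
    classification = np.empty((len(grid_y), len(grid_x)), dtype=object)
    for iy, vy in enumerate(grid_y):
        p_row, c_row = set_parameter(params, coupling, param_y, vy)
        row = sweep_1d(param_x, grid_x, p_row, c_row, signal=signal,
                       mode="independent", n_ic=n_ic, t_end=t_end,
                       dt_out=dt_out, seed=seed + iy)
        classification[iy] = row.classification
    return Region2D(param_x=param_x, param_y=param_y, grid_x=grid_x,
                    grid_y=grid_y, classification=classification)


def pulse_response(params: ParameterSet, coupling: CouplingParams,
                   pulse: SignalSpec, x0, t_pulse: float = 40.0,
                   t_relax: float = 110.0,
                   dt_out: float = 0.01) -> tuple[Trajectory, str]:
    """Drive the system with a pulsed cyclin-synthesis input and classify.

    The pulse signal acts during ``[0, t_pulse]``; afterwards the input
    returns to the constant baseline ``params.alpha1``.  The verdict
    compares the pre-pulse state with the post-relaxation attractor:

    * ``"oscillates"`` — post-stimulus attractor is a limit cycle;
    * ``"switched-and-stuck"`` — ends on a steady branch displaced from
      the starting level by more than ``BRANCH_TOL``;
    * ``"switched-up"`` — C_1 rose above the starting level by more than
      ``BRANCH_TOL`` during the pulse but relaxed back;
    * ``"unchanged"`` — no excursion beyond ``BRANCH_TOL`` at all.
    """
    x0 = np.asarray(x0, dtype=float)
    during = integrate_deterministic(params, coupling, pulse, x0, t_pulse,
                                     dt_out=dt_out)
    after = integrate_deterministic(params, coupling, params.alpha1,
                                    during.final_state(), t_relax,
                                    dt_out=dt_out)
    traj = Trajectory(
        times=np.concatenate([during.times, after.times + t_pulse]),
        states=np.vstack([during.states, after.states]),
        meta={**during.meta, "pulse": pulse, "t_pulse": t_pulse})
    c_start = float(x0[0])
    kind, lo, hi = _attractor_of(after)
    peak_during = float(during.observable("C", 0).max())
    if kind == "oscillatory":
        verdict = "oscillates"
    elif abs((lo + hi) / 2 - c_start) > BRANCH_TOL:
        verdict = "switched-and-stuck"
    elif peak_during - c_start > BRANCH_TOL:
        verdict = "switched-up"
    else:
        verdict = "unchanged"
    return traj, verdict
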