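"""Numerical integration and trajectory summaries.

The deterministic solver is LSODA (stiff-capable, adaptive) with piecewise
restarts at stimulus discontinuities so square-wave edges are never stepped
across.  The intrinsic-noise solver is Euler--Maruyama with additive
Gaussian increments on every state component, clipped to the physical box
(C, R >= 0; P, A in [0, 1]).

`summarize_oscillation` classifies the late-time attractor of a reference
observable (active CDK1 of cell 1 by default) as steady or oscillatory and
extracts the mean period and per-cycle amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .model import coupled_rhs, single_cell_rhs
from .params import CouplingParams, ParameterSet
from .signals import SignalSpec, signal_breakpoints

__all__ = [
    "Trajectory", "NoiseSpec", "OscillationSummary",
    "IntegrationError", "InsufficientDataError",
    "draw_initial_conditions", "integrate_deterministic",
    "integrate_stochastic", "summarize_oscillation",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Solver failure; carries the last time reached in ``last_t``."""

    def __init__(self, message: str, last_t: float | None = None):
        super().__init__(message)
        self.last_t = last_t


class InsufficientDataError(ValueError):
    """Trajectory too short for the requested analysis."""


@dataclass
class NoiseSpec:
    """Additive intrinsic noise: increment SD = intensity * sqrt(dt)."""

    intensity: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.intensity < 0:
            raise ValueError("noise intensity must be >= 0")


@dataclass
class Trajectory:
    """Sampled solution: times (n,), states (n, d); d = 3N+1 coupled, 3 single."""

    times: np.ndarray
    states: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def N(self) -> int:
        d = self.states.shape[1]
        return 1 if d == 3 else (d - 1) // 3

    @property
    def coupled(self) -> bool:
        return self.states.shape[1] != 3

    def observable(self, name: str = "C", cell: int = 0) -> np.ndarray:
        """Time series of one observable; name in {C, P, A, R}."""
        if not self.coupled:
            idx = {"C": 0, "P": 1, "A": 2}[name]
            return self.states[:, idx]
        N = self.N
        if name == "R":
            return self.states[:, 3 * N]
        off = {"C": 0, "P": N, "A": 2 * N}[name]
        return self.states[:, off + cell]

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()


@dataclass
class OscillationSummary:
    """Attractor class plus period/amplitude of the reference observable."""

    attractor: str  # "oscillatory" | "steady" | "undetermined"
    period: float | None = None
    amplitude: float | None = None
    n_peaks: int = 0
    reference: str = "C1"


def draw_initial_conditions(coupling: CouplingParams, seed: int,
                            spread: float | None = None,
                            r0: float = 0.0) -> np.ndarray:
    """Seeded random initial state for the coupled system.

    Default (``spread=None``): each cell's (C, P, A) drawn independently
    from Uniform(0, 1); R(0) = ``r0``.  With ``spread`` set, all cells
    share one Uniform(0,1)^3 base point and receive independent
    Uniform(-spread/2, spread/2) jitter (clipped to [0, 1]) — a nearly
    synchronized start used to probe persistence of synchrony.
    """
    rng = np.random.default_rng(seed)
    N = coupling.N
    if spread is None:
        cpa = rng.uniform(0.0, 1.0, (3, N))
    else:
        base = rng.uniform(0.0, 1.0, 3)
        jitter = rng.uniform(-spread / 2, spread / 2, (3, N))
        cpa = np.clip(base[:, None] + jitter, 0.0, 1.0)
    return np.concatenate([cpa[0], cpa[1], cpa[2], [r0]])


def _as_signal(signal) -> SignalSpec:
    if isinstance(signal, SignalSpec):
        return signal
    return SignalSpec(kind="constant", aq=float(signal))


def integrate_deterministic(params: ParameterSet,
                            coupling: CouplingParams | None,
                            signal, x0, t_end: float,
                            dt_out: float = 0.01,
                            t_start: float = 0.0,
                            rtol: float = DEFAULT_RTOL,
                            atol: float = DEFAULT_ATOL) -> Trajectory:
    """Integrate the deterministic model and sample every ``dt_out`` min.

    ``coupling=None`` integrates the 3-variable single-cell model (x0 of
    length 3); otherwise the flat coupled state of length 3N+1.  The time
    span is split at stimulus discontinuities; for noise stimuli the solver
    step is capped at the noise grid width instead.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    sig = _as_signal(signal)
    x0 = np.asarray(x0, dtype=float)
    if coupling is None:
        rhs = lambda t, y: single_cell_rhs(y, t, params, sig)
        if x0.shape != (3,):
            raise ValueError("single-cell state must have length 3")
    else:
        rhs = lambda t, y: coupled_rhs(y, t, params, coupling, sig)
        if x0.shape != (3 * coupling.N + 1,):
            raise ValueError(
                f"coupled state must have length {3 * coupling.N + 1}")

    edges = signal_breakpoints(sig, t_end)
    edges = edges[edges > t_start]
    seg_bounds = np.concatenate([[t_start], edges, [t_end]])
    max_step = sig.dt_signal if sig.kind == "noise" else np.inf

    times = np.arange(t_start, t_end + 0.5 * dt_out, dt_out)
    times = times[times <= t_end]
    states = np.empty((len(times), len(x0)))
    y = x0
    filled = 0
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        in_seg = times[(times <= b) & (np.arange(len(times)) >= filled)]
        # always evaluate at b so the next segment restarts exactly there
        extra = in_seg.size == 0 or in_seg[-1] < b
        t_eval = np.append(in_seg, b) if extra else in_seg
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol, max_step=max_step)
        if not sol.success:
            raise IntegrationError(
                f"LSODA failed on [{a}, {b}]: {sol.message}",
                last_t=sol.t[-1] if sol.t.size else a)
        keep = sol.t.size - (1 if extra else 0)
        states[filled:filled + keep] = sol.y[:, :keep].T
        filled += keep
        y = sol.y[:, -1]
    if filled != len(times):  # pragma: no cover - defensive
        times = times[:filled]
        states = states[:filled]
    meta = {"params": params.as_dict(),
            "coupling": coupling.as_dict() if coupling else None,
            "signal": sig, "rtol": rtol, "atol": atol, "dt_out": dt_out}
    return Trajectory(times=times, states=states, meta=meta)


def integrate_stochastic(params: ParameterSet,
                         coupling: CouplingParams | None,
                         signal, x0, t_end: float,
                         dt: float = 1e-3,
                         noise: NoiseSpec | None = None,
                         dt_out: float = 0.01,
                         t_start: float = 0.0) -> Trajectory:
    """Euler--Maruyama path with additive intrinsic noise.

    Every state component receives an independent Gaussian increment of
    standard deviation ``intensity * sqrt(dt)`` per step; after each step
    the state is clipped to the physical box.  ``intensity = 0`` reduces to
    plain Euler integration of the deterministic system.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    noise = noise or NoiseSpec(intensity=0.0)
    sig = _as_signal(signal)
    x0 = np.asarray(x0, dtype=float)
    single = coupling is None
    if single:
        rhs = lambda t, y: single_cell_rhs(y, t, params, sig)
        lo = np.array([0.0, 0.0, 0.0])
        hi = np.array([np.inf, 1.0, 1.0])
    else:
        N = coupling.N
        rhs = lambda t, y: coupled_rhs(y, t, params, coupling, sig)
        lo = np.zeros(3 * N + 1)
        hi = np.concatenate([np.full(N, np.inf), np.ones(2 * N),
                             [np.inf]])
    rng = np.random.default_rng(noise.seed)
    sd = noise.intensity * np.sqrt(dt)
    n_steps = int(round((t_end - t_start) / dt))
    stride = max(1, int(round(dt_out / dt)))
    n_out = n_steps // stride + 1
    times = t_start + np.arange(n_out) * stride * dt
    states = np.empty((n_out, len(x0)))
    states[0] = x0
    y = x0.copy()
    t = t_start
    out = 1
    for i in range(1, n_steps + 1):
        y = y + rhs(t, y) * dt
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=y.shape)
        np.clip(y, lo, hi, out=y)
        t = t_start + i * dt
        if i % stride == 0:
            states[out] = y
            out += 1
    meta = {"params": params.as_dict(),
            "coupling": coupling.as_dict() if coupling else None,
            "signal": sig, "dt": dt, "dt_out": dt_out,
            "noise": {"intensity": noise.intensity, "seed": noise.seed}}
    return Trajectory(times=times, states=states[:out], meta=meta)


def summarize_oscillation(traj: Trajectory,
                          transient_fraction: float = 0.5,
                          reference: str = "C", cell: int = 0,
                          steady_span: float = 1e-4,
                          min_peaks: int = 10,
                          cv_tol: float = 0.01) -> OscillationSummary:
    """Classify the late-time attractor and measure period and amplitude.

    The first ``transient_fraction`` of the trajectory is discarded.  The
    attractor is *steady* when the remaining peak-to-trough span falls
    below ``steady_span``; *oscillatory* when at least ``min_peaks`` peaks
    are found with inter-peak-interval coefficient of variation below
    ``cv_tol``; otherwise *undetermined*.  Period is the mean inter-peak
    interval; amplitude the mean max-min per full cycle.
    """
    if len(traj.times) < 10:
        raise InsufficientDataError("trajectory has fewer than 10 samples")
    t = traj.times
    x = traj.observable(reference, cell)
    cut = t[0] + transient_fraction * (t[-1] - t[0])
    sel = t >= cut
    t, x = t[sel], x[sel]
    ref_name = f"{reference}{cell + 1}" if traj.coupled else reference
    span = float(x.max() - x.min())
    if span < steady_span:
        return OscillationSummary(attractor="steady", reference=ref_name)
    peaks, _ = find_peaks(x, prominence=0.1 * span)
    if len(peaks) < 3:
        return OscillationSummary(attractor="undetermined",
                                  n_peaks=len(peaks), reference=ref_name)
    ipi = np.diff(t[peaks])
    cv = float(ipi.std() / ipi.mean())
    period = float(ipi.mean())
    amps = [float(x[a:b + 1].max() - x[a:b + 1].min())
            for a, b in zip(peaks[:-1], peaks[1:])]
    amplitude = float(np.mean(amps))
    if len(peaks) >= min_peaks and cv < cv_tol:
        return OscillationSummary(attractor="oscillatory", period=period,
                                  amplitude=amplitude, n_peaks=len(peaks),
                                  reference=ref_name)
    return OscillationSummary(attractor="undetermined", period=period,
                              amplitude=amplitude, n_peaks=len(peaks),
                              reference=ref_name)
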