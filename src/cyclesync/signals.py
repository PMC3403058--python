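"""Time-varying cyclin-synthesis stimuli alpha1(t).

Four waveforms drive the CDK1 synthesis term: a constant input, a
square-wave pulse train (on for t1 of every t0 minutes), a half-wave
rectified sinusoid of unit angular frequency, and a noisy constant
(uniform noise held piecewise-constant on a fixed grid so that the ODE
right-hand side stays deterministic for a given seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SignalSpec", "eval_signal", "default_bq", "signal_breakpoints"]

_KINDS = ("constant", "square", "sine", "noise")


@dataclass(frozen=True)
class SignalSpec:
    """Specification of the cyclin-synthesis input alpha1(t).

    Parameters
    ----------
    kind : {"constant", "square", "sine", "noise"}
    aq : float
        Signal strength (concentration/min).
    t0, t1 : float
        Square-wave period and on-duration (min).  On when
        ``mod(t, t0) < t1``.
    bq : float or None
        Noise amplitude.  ``None`` resolves via :func:`default_bq`.
    seed : int
        Seed of the noise stream (ignored by deterministic kinds).
    dt_signal : float
        Width of the piecewise-constant noise grid (min).
    """

    kind: str = "constant"
    aq: float = 0.1
    t0: float = 4.0
    t1: float = 2.0
    bq: float | None = None
    seed: int = 0
    dt_signal: float = 0.1

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown signal kind {self.kind!r}; "
                             f"expected one of {_KINDS}")
        if self.aq < 0:
            raise ValueError("aq must be >= 0")
        if self.kind == "square" and not (0 < self.t1 <= self.t0):
            raise ValueError("square wave requires 0 < t1 <= t0")
        if self.bq is not None and self.bq < 0:
            raise ValueError("bq must be >= 0")

    def replace(self, **kw) -> "SignalSpec":
        return replace(self, **kw)

    @property
    def resolved_bq(self) -> float:
        if self.bq is not None:
            return self.bq
        return default_bq(self.aq) if self.kind == "noise" else 0.0

    def __call__(self, t):
        return eval_signal(self, t)


def default_bq(aq: float) -> float:
    """Noise amplitude paired with a given mean strength.

    0.001 for mean strengths up to 0.01, 0.01 above.
    """
    if aq <= 0:
        raise ValueError("aq must be > 0")
    return 0.001 if aq <= 0.01 else 0.01


# Per-seed cache of the uniform noise stream; bin i of a stream is the
# i-th variate of default_rng(seed), so draws are independent of the order
# in which the integrator visits bins.
_noise_cache: dict[int, np.ndarray] = {}


def _noise_stream(seed: int, nbins: int) -> np.ndarray:
    buf = _noise_cache.get(seed)
    if buf is None or buf.size < nbins:
        size = max(1024, 2 ** int(math.ceil(math.log2(max(nbins, 2)))))
        _noise_cache[seed] = np.random.default_rng(seed).random(size)
        buf = _noise_cache[seed]
    return buf


def eval_signal(spec: SignalSpec, t):
    """Evaluate alpha1(t).  Accepts scalar or array t (>= 0)."""
    t = np.asarray(t, dtype=float)
    if spec.kind == "constant":
        out = np.full_like(t, spec.aq)
    elif spec.kind == "square":
        out = np.where(np.mod(t, spec.t0) < spec.t1, spec.aq, 0.0)
    elif spec.kind == "sine":
        s = np.sin(t)
        out = np.where(s > 0, spec.aq * s, 0.0)
    else:  # noise
        idx = np.floor_divide(t, spec.dt_signal).astype(np.int64)
        u = _noise_stream(spec.seed, int(idx.max()) + 1 if idx.size else 1)
        out = spec.aq + spec.resolved_bq * u[idx]
    return float(out) if out.ndim == 0 else out


def signal_breakpoints(spec: SignalSpec, t_end: float) -> np.ndarray:
    """Times in (0, t_end) where alpha1(t) is discontinuous or kinked.

    Used by the deterministic integrator to restart at square-wave edges
    (and sinusoid clipping points) instead of stepping across them.
    """
    if spec.kind == "square":
        edges = []
        m = 0
        while m * spec.t0 < t_end:
            for e in (m * spec.t0, m * spec.t0 + spec.t1):
                if 0 < e < t_end:
                    edges.append(e)
            m += 1
        return np.asarray(sorted(set(edges)))
    if spec.kind == "sine":
        n = int(t_end / math.pi) + 1
        pts = np.arange(1, n + 1) * math.pi
        return pts[pts < t_end]
    return np.empty(0)
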