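"""Right-hand sides of the single-cell and globally coupled oscillator.

State layout for the coupled system of N cells is the flat vector
``y = [C_1..C_N, P_1..P_N, A_1..A_N, R]`` (length 3N+1).  C is active
cyclin--CDK1, P the active Plk1 fraction, A the active APC fraction and R
the shared coupling species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CouplingParams, ParameterSet
from .signals import SignalSpec, eval_signal

__all__ = ["SystemState", "hill", "dhill_dx", "dhill_dK",
           "single_cell_rhs", "coupled_rhs", "pack_state", "unpack_state"]


@dataclass
class SystemState:
    """Concentrations of an N-cell system: per-cell C, P, A plus shared R."""

    C: np.ndarray
    P: np.ndarray
    A: np.ndarray
    R: float

    @property
    def N(self) -> int:
        return len(self.C)

    def to_vector(self) -> np.ndarray:
        return pack_state(self.C, self.P, self.A, self.R)

    @classmethod
    def from_vector(cls, y: np.ndarray, N: int) -> "SystemState":
        C, P, A, R = unpack_state(y, N)
        return cls(C=C, P=P, A=A, R=R)


def pack_state(C, P, A, R) -> np.ndarray:
    return np.concatenate([np.atleast_1d(C), np.atleast_1d(P),
                           np.atleast_1d(A), [R]])


def unpack_state(y: np.ndarray, N: int):
    if len(y) != 3 * N + 1:
        raise ValueError(f"state length {len(y)} does not match 3*{N}+1")
    return y[:N], y[N:2 * N], y[2 * N:3 * N], float(y[3 * N])


def hill(x, K, n):
    """x^n / (K^n + x^n), exactly 0 at x <= 0 (avoids 0/0 at the origin)."""
    xn = np.where(np.asarray(x, dtype=float) > 0, x, 0.0) ** n
    return xn / (K ** n + xn)


def dhill_dx(x, K, n):
    """d/dx of hill(x, K, n); 0 at x <= 0 for n > 1."""
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    xn = x ** n
    return n * x ** (n - 1) * K ** n / (K ** n + xn) ** 2


def dhill_dK(x, K, n):
    """d/dK of hill(x, K, n)."""
    xn = np.where(np.asarray(x, dtype=float) > 0, x, 0.0) ** n
    return -n * K ** (n - 1) * xn / (K ** n + xn) ** 2


def _check_finite(y):
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite state encountered: {y!r}")


def single_cell_rhs(state, t: float, params: ParameterSet,
                    signal: SignalSpec | float) -> np.ndarray:
    """Time derivative (dC, dP, dA) of one uncoupled oscillator.

    dC/dt = alpha1(t) - beta1 * C * A^n1/(K1^n1 + A^n1)
    dP/dt = alpha2 (1-P) C^n2/(K2^n2 + C^n2) - beta2 P
    dA/dt = alpha3 (1-A) P^n3/(K3^n3 + P^n3) - beta3 A
    """
    y = np.asarray(state, dtype=float)
    _check_finite(y)
    C, P, A = y
    a1 = eval_signal(signal, t) if isinstance(signal, SignalSpec) else signal
    dC = a1 - params.beta1 * C * hill(A, params.K1, params.n1)
    dP = params.alpha2 * (1 - P) * hill(C, params.K2, params.n2) \
        - params.beta2 * P
    dA = params.alpha3 * (1 - A) * hill(P, params.K3, params.n3) \
        - params.beta3 * A
    return np.array([dC, dP, dA])


def coupled_rhs(y, t: float, params: ParameterSet, coupling: CouplingParams,
                signal: SignalSpec | float) -> np.ndarray:
    """Time derivative of the flat coupled state [C, P, A, R].

    Per-cell dynamics equal the single-cell model plus the common drive
    k * R^n/(KL^n + R^n) on dC_i/dt; the medium evolves as
    dR/dt = (k0/N) * sum_i C_i^n/(Ka^n + C_i^n) - km * R.
    """
    y = np.asarray(y, dtype=float)
    _check_finite(y)
    N = coupling.N
    C, P, A, R = unpack_state(y, N)
    a1 = eval_signal(signal, t) if isinstance(signal, SignalSpec) else signal
    drive = coupling.k * hill(R, coupling.KL, coupling.n)
    dC = a1 - params.beta1 * C * hill(A, params.K1, params.n1) + drive
    dP = params.alpha2 * (1 - P) * hill(C, params.K2, params.n2) \
        - params.beta2 * P
    dA = params.alpha3 * (1 - A) * hill(P, params.K3, params.n3) \
        - params.beta3 * A
    dR = (coupling.k0 / N) * hill(C, coupling.Ka, coupling.n).sum() \
        - coupling.km * R
    return np.concatenate([dC, dP, dA, [dR]])
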