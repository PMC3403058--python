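"""Kinetic parameters of the single-cell and coupled cell-cycle oscillator.

The single-cell model is a three-variable negative-feedback loop: active
cyclin--CDK1 (C) activates Plk1 (P), Plk1 activates APC (A), and APC
inactivates CDK1.  Activation steps are Hill functions; Plk1 and APC are
conserved (active fraction in [0, 1]).  N identical cells are coupled
through a common medium species R that is produced from the Hill-transformed
mean CDK1 activity and feeds back positively on every cell's CDK1.

All rates are per minute; concentrations are dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

__all__ = [
    "ParameterSet",
    "CouplingParams",
    "table1",
    "table1_coupling",
    "validate_params",
    "load_params",
    "dump_params",
    "TABLE1_PATH",
]

TABLE1_PATH = Path(__file__).parent / "data" / "table1.yaml"


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic constants of the single-cell CDK1--Plk1--APC oscillator.

    alpha1 is the baseline cyclin-synthesis (CDK1 activation) rate; it is
    overridden at run time when a time-varying stimulus is attached.
    alpha2/alpha3 are the Plk1/APC activation rate constants, beta1..beta3
    the inactivation rate constants, K1..K3 the Hill activation coefficients
    and n1..n3 the (integer) Hill exponents.
    """

    alpha1: float = 0.1
    alpha2: float = 3.0
    alpha3: float = 3.0
    beta1: float = 3.0
    beta2: float = 1.0
    beta3: float = 1.0
    K1: float = 0.5
    K2: float = 0.5
    K3: float = 0.5
    n1: int = 4
    n2: int = 4
    n3: int = 4

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class CouplingParams:
    """Global (mean-field) coupling through the shared medium species R.

    Each cell's CDK1 gains the drive k * R^n / (KL^n + R^n); R is produced
    at rate (k0 / N) * sum_i C_i^n / (Ka^n + C_i^n) and degraded linearly
    at rate km.  N is the number of cells.
    """

    k: float = 1.0
    KL: float = 0.5
    n: int = 3
    k0: float = 2.0
    Ka: float = 0.5
    km: float = 1.5
    N: int = 10

    def replace(self, **kw) -> "CouplingParams":
        return replace(self, **kw)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def table1() -> ParameterSet:
    """Default single-cell parameters (the published operating point)."""
    return ParameterSet()


def table1_coupling(N: int = 10) -> CouplingParams:
    """Default coupling parameters for N identical cells."""
    return CouplingParams(N=N)


_POSITIVE_P = ("alpha1", "alpha2", "alpha3", "beta1", "beta2", "beta3",
               "K1", "K2", "K3")
_EXPONENTS_P = ("n1", "n2", "n3")
_POSITIVE_C = ("k", "KL", "k0", "Ka", "km")


def validate_params(params: ParameterSet,
                    coupling: CouplingParams | None = None) -> list[str]:
    """Check every model invariant; return a list of violation messages.

    Empty list means the configuration is valid.  Never raises: callers that
    want a hard failure should raise on a non-empty result.
    """
    problems: list[str] = []
    for name in _POSITIVE_P:
        v = getattr(params, name)
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
            problems.append(f"{name} must be > 0 and finite (got {v!r})")
    for name in _EXPONENTS_P:
        v = getattr(params, name)
        if not (float(v).is_integer() and v >= 1):
            problems.append(f"{name} must be an integer >= 1 (got {v!r})")
    if coupling is not None:
        for name in _POSITIVE_C:
            v = getattr(coupling, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                problems.append(f"{name} must be > 0 and finite (got {v!r})")
        if not (float(coupling.n).is_integer() and coupling.n >= 1):
            problems.append(f"n must be an integer >= 1 (got {coupling.n!r})")
        if not (float(coupling.N).is_integer() and coupling.N >= 1):
            problems.append(f"N must be an integer >= 1 (got {coupling.N!r})")
    return problems


def load_params(path: str | Path) -> tuple[ParameterSet, CouplingParams]:
    """Read a flat key--value YAML/JSON parameter file.

    Keys are exactly the field names of :class:`ParameterSet` and
    :class:`CouplingParams` (``alpha1`` ... ``n3``, ``k``, ``KL``, ``n``,
    ``k0``, ``Ka``, ``km``, ``N``).  Missing keys fall back to defaults;
    unknown keys raise ``KeyError``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    p_names = {f.name for f in fields(ParameterSet)}
    c_names = {f.name for f in fields(CouplingParams)}
    unknown = set(raw) - p_names - c_names
    if unknown:
        raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
    params = ParameterSet(**{k: v for k, v in raw.items() if k in p_names})
    coupling = CouplingParams(**{k: v for k, v in raw.items() if k in c_names})
    return params, coupling


def dump_params(params: ParameterSet, coupling: CouplingParams,
                path: str | Path) -> None:
    """Write parameters as a flat YAML mapping (inverse of load_params)."""
    merged = {**params.as_dict(), **coupling.as_dict()}
    with open(path, "w") as fh:
        yaml.safe_dump(merged, fh, sort_keys=False)
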