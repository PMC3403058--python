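"""Experiment configuration files and reproducible fixture generation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .params import CouplingParams, ParameterSet, validate_params
from .robustness import latin_hypercube_sample
from .signals import SignalSpec
from .simulate import draw_initial_conditions

__all__ = ["ConfigError", "ExperimentConfig", "load_config",
           "make_fixtures"]


class ConfigError(ValueError):
    """Invalid experiment configuration; names the offending key."""


@dataclass
class ExperimentConfig:
    """Validated model + signal + run settings for one experiment."""

    params: ParameterSet
    coupling: CouplingParams
    signal: SignalSpec
    t_end: float = 500.0
    dt_out: float = 0.01
    seed: int = 0
    noise_intensity: float = 0.0
    rtol: float = 1e-8
    atol: float = 1e-10
    analysis: dict = field(default_factory=dict)

    def echo(self, path: str | Path) -> None:
        """Write the fully resolved configuration next to the outputs."""
        from dataclasses import asdict
        doc = {"model": {**self.params.as_dict(), **self.coupling.as_dict()},
               "signal": asdict(self.signal),
               "run": {"t_end": self.t_end, "dt_out": self.dt_out,
                       "seed": self.seed,
                       "noise_intensity": self.noise_intensity,
                       "rtol": self.rtol, "atol": self.atol},
               "analysis": self.analysis}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _pick(block: dict, cls, label: str):
    names = {f.name for f in fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in {label} block: "
                          f"{sorted(unknown)}")
    return {k: v for k, v in block.items() if k in names}


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML/JSON experiment config.

    Layout: a ``model`` block with flat parameter keys, an optional
    ``signal`` block (defaults to the constant baseline input), and an
    optional ``run`` block (t_end, dt_out, seed, noise_intensity,
    tolerances).  Any violated model invariant raises :class:`ConfigError`
    naming the key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model = raw.get("model", raw if "signal" not in raw
                    and "run" not in raw else {})
    p_names = {f.name for f in fields(ParameterSet)}
    c_names = {f.name for f in fields(CouplingParams)}
    unknown = set(model) - p_names - c_names
    if unknown:
        raise ConfigError(f"unknown key(s) in model block: "
                          f"{sorted(unknown)}")
    params = ParameterSet(**{k: v for k, v in model.items()
                             if k in p_names})
    coupling = CouplingParams(**{k: v for k, v in model.items()
                                 if k in c_names})
    problems = validate_params(params, coupling)
    if problems:
        raise ConfigError("; ".join(problems))
    sig_block = raw.get("signal", {})
    try:
        signal = SignalSpec(**_pick(sig_block, SignalSpec, "signal")) \
            if sig_block else SignalSpec(kind="constant", aq=params.alpha1)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    run = raw.get("run", {})
    known_run = {"t_end", "dt_out", "seed", "noise_intensity",
                 "rtol", "atol"}
    unknown = set(run) - known_run
    if unknown:
        raise ConfigError(f"unknown key(s) in run block: {sorted(unknown)}")
    return ExperimentConfig(params=params, coupling=coupling, signal=signal,
                            analysis=raw.get("analysis", {}), **run)


def make_fixtures(kind: str, out_dir: str | Path, seed: int = 0,
                  N: int = 10, variation: float = 0.1,
                  n: int = 100) -> list[Path]:
    """Write seeded, reproducible fixture files used by tests and examples.

    ``kind="ics"`` — a CSV bank of random initial conditions;
    ``kind="params"`` — a CSV Latin-hypercube parameter bank within
    ±variation of the defaults; ``kind="signals"`` — one YAML per stimulus
    family at its default strength.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "ics":
        coupling = CouplingParams(N=N)
        rows = [draw_initial_conditions(coupling, s)
                for s in np.random.SeedSequence(seed).generate_state(n)
                .astype(int) % (2 ** 31)]
        path = out_dir / f"ics_N{N}_seed{seed}.csv"
        header = ",".join([f"C{i+1}" for i in range(N)]
                          + [f"P{i+1}" for i in range(N)]
                          + [f"A{i+1}" for i in range(N)] + ["R"])
        np.savetxt(path, np.array(rows), delimiter=",", header=header,
                   comments="", fmt="%.17g")
        written.append(path)
    elif kind == "params":
        draws = latin_hypercube_sample(ParameterSet(), CouplingParams(),
                                       variation, n, seed)
        path = out_dir / f"params_var{int(variation*100)}_seed{seed}.csv"
        keys = list(draws[0][0].as_dict()) + list(draws[0][1].as_dict())
        rows = [{**p.as_dict(), **c.as_dict()} for p, c in draws]
        with open(path, "w") as fh:
            fh.write(",".join(keys) + "\n")
            for row in rows:
                fh.write(",".join(f"{row[k]:.17g}"
                                  if isinstance(row[k], float)
                                  else str(row[k]) for k in keys) + "\n")
        written.append(path)
    elif kind == "signals":
        presets = [SignalSpec(kind="constant", aq=0.1),
                   SignalSpec(kind="square", aq=0.6, t0=4.0, t1=2.0),
                   SignalSpec(kind="sine", aq=1.0),
                   SignalSpec(kind="noise", aq=0.01, seed=seed)]
        from dataclasses import asdict
        for spec in presets:
            path = out_dir / f"signal_{spec.kind}.yaml"
            with open(path, "w") as fh:
                yaml.safe_dump(asdict(spec), fh, sort_keys=False)
            written.append(path)
    else:
        raise ConfigError(f"unknown fixture kind {kind!r}")
    return written
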