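"""Result serialization: tidy trajectory CSV plus JSON metadata sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import SignalSpec
from .simulate import Trajectory

__all__ = ["trajectory_to_frame", "write_trajectory", "read_trajectory",
           "write_json", "scan_to_frame", "sweep_to_frame"]


def _jsonable(obj):
    if isinstance(obj, SignalSpec):
        return {"__signal__": dataclasses.asdict(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format frame: one row per (time, cell) with C, P, A and R."""
    N = traj.N
    t = traj.times
    if not traj.coupled:
        return pd.DataFrame({"time": t, "cell": 1,
                             "C": traj.states[:, 0],
                             "P": traj.states[:, 1],
                             "A": traj.states[:, 2],
                             "R": np.nan})
    frames = []
    R = traj.states[:, 3 * N]
    for i in range(N):
        frames.append(pd.DataFrame({
            "time": t, "cell": i + 1,
            "C": traj.states[:, i],
            "P": traj.states[:, N + i],
            "A": traj.states[:, 2 * N + i],
            "R": R}))
    return pd.concat(frames, ignore_index=True)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """CSV at ``path`` plus a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    trajectory_to_frame(traj).to_csv(path, index=False)
    write_json(traj.meta, path.with_suffix(path.suffix + ".meta.json"))


def read_trajectory(path: str | Path) -> Trajectory:
    """Inverse of :func:`write_trajectory`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cells = sorted(df["cell"].unique())
    N = len(cells)
    times = df[df["cell"] == cells[0]]["time"].to_numpy()
    if N == 1 and df["R"].isna().all():
        sub = df[df["cell"] == 1]
        states = np.column_stack([sub["C"], sub["P"], sub["A"]])
    else:
        cols = []
        for var in ("C", "P", "A"):
            for i in cells:
                cols.append(df[df["cell"] == i][var].to_numpy())
        cols.append(df[df["cell"] == cells[0]]["R"].to_numpy())
        states = np.column_stack(cols)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        sig = meta.get("signal")
        if isinstance(sig, dict) and "__signal__" in sig:
            meta["signal"] = SignalSpec(**sig["__signal__"])
    return Trajectory(times=times, states=states, meta=meta)


def scan_to_frame(scan) -> pd.DataFrame:
    """Per-point table of an interval scan (for the Table-2-style output)."""
    return pd.DataFrame({
        "parameter": scan.parameter,
        "value": scan.grid,
        "synchronized": scan.synchronized_mask,
        "amplitude_death": scan.amplitude_death_mask,
        "period": scan.period,
        "amplitude": scan.amplitude,
    })


def sweep_to_frame(sweep) -> pd.DataFrame:
    """Per-point table of a 1-D bifurcation sweep."""
    return pd.DataFrame({
        "parameter": sweep.parameter,
        "value": sweep.grid,
        "class": sweep.classification,
        "c1_min": sweep.cmin,
        "c1_max": sweep.cmax,
        "mode": sweep.mode,
        "direction": sweep.direction,
    })
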