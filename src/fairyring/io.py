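"""Configuration files and trajectory serialization.

Config files are YAML mirroring :class:`~fairyring.engine.SimConfig` field
names, with model parameters under a ``params`` mapping keyed by the
published symbols (``g_F``, ``s_I``, ``k_W``, ...)::

    params: {g_F: 0.05, W: 1.0}
    hypothesis_mode: combined
    shape: [400]
    n_steps: 2000

Trajectories round-trip through two formats: a long delimited table (one row
per cell per snapshot) and a compact ``.npz`` gridded archive.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import available_water
from .engine import SimConfig, StateFields, Trajectory, FIELD_NAMES
from .params import ModelParams

__all__ = [
    "load_config",
    "dump_config",
    "trajectory_to_frame",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "save_trajectory_npz",
    "load_trajectory_npz",
]

_SIMPLE_KEYS = (
    "dx", "dt", "n_steps", "inoculum_amount", "initial_plant",
    "snapshot_stride", "front_threshold", "hypothesis_mode",
)


def load_config(path) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_mapping(raw)


def config_from_mapping(raw: dict) -> SimConfig:
    raw = dict(raw)
    kwargs = {}
    params = raw.pop("params", {}) or {}
    kwargs["params"] = ModelParams.from_dict(params)
    if "shape" in raw:
        shape = raw.pop("shape")
        kwargs["shape"] = tuple(int(n) for n in (shape if isinstance(shape, (list, tuple)) else [shape]))
    if "inoculum_site" in raw:
        site = raw.pop("inoculum_site")
        if site is not None:
            site = tuple(int(i) for i in (site if isinstance(site, (list, tuple)) else [site]))
        kwargs["inoculum_site"] = site
    for key in _SIMPLE_KEYS:
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ValueError(f"unknown config key(s): {sorted(raw)}")
    return SimConfig(**kwargs)


def dump_config(config: SimConfig, path) -> None:
    data = {
        "params": config.params.as_dict(),
        "shape": list(config.shape),
        "inoculum_site": None if config.inoculum_site is None else list(config.inoculum_site),
    }
    for key in _SIMPLE_KEYS:
        data[key] = getattr(config, key)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-form table: one row per cell per snapshot with columns
    time, x[, y], F, I, T, S, P, N, W_bar."""
    params = traj.config.resolved_params()
    frames = []
    for t, snap in zip(traj.times, traj.snapshots):
        cols: dict[str, np.ndarray] = {"time": np.full(snap.F.size, float(t))}
        if len(snap.shape) == 1:
            cols["x"] = np.arange(snap.shape[0]) * snap.dx
        else:
            yy, xx = np.meshgrid(
                np.arange(snap.shape[0]) * snap.dx,
                np.arange(snap.shape[1]) * snap.dx,
                indexing="ij",
            )
            cols["x"] = xx.ravel()
            cols["y"] = yy.ravel()
        for name in FIELD_NAMES:
            cols[name] = getattr(snap, name).ravel()
        cols["W_bar"] = available_water(snap.F, params).ravel()
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_trajectory_npz(traj: Trajectory, path) -> None:
    """Compact gridded archive: stacked (time, *grid) arrays per field."""
    arrays = {
        name: np.stack([getattr(s, name) for s in traj.snapshots])
        for name in FIELD_NAMES
    }
    np.savez_compressed(
        path,
        times=traj.times,
        front_positions=traj.front_positions,
        dx=np.asarray(traj.config.dx),
        **arrays,
    )


def load_trajectory_npz(path, config: SimConfig | None = None) -> Trajectory:
    """Rebuild a :class:`Trajectory` from an ``.npz`` archive.

    ``config`` restores full provenance; when omitted, a minimal config
    matching the stored grid is synthesized (sufficient for plotting and
    biometrics, not for provenance)."""
    with np.load(path) as data:
        times = data["times"]
        fronts = data["front_positions"]
        dx = float(data["dx"])
        stacks = {name: data[name] for name in FIELD_NAMES}
    n_snap = len(times)
    snaps = [
        StateFields(*(stacks[name][k] for name in FIELD_NAMES), dx=dx)
        for k in range(n_snap)
    ]
    if config is None:
        config = SimConfig(
            shape=snaps[0].shape, dx=dx,
            n_steps=max(1, int(round(times[-1] / max(times[1] - times[0], 1.0)))),
        )
    return Trajectory(times=times, snapshots=snaps, front_positions=fronts, config=config)
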