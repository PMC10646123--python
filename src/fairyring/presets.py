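"""Canned experiments: the published panel sweeps, the type-1.3 showcase,
the ring-vs-disk contrast and the sensitivity heatmap.

Panel grids span the published parameter ranges: soil water ``W`` in
[0.1, 2] (6 levels), fungal growth ``g_F`` in [0.01, 0.05] (5 levels) and,
where phytotoxicity is active, plant toxin sensitivity ``s_T`` over its
mode-specific range. Every preset resolves to concrete
:class:`~fairyring.engine.SimConfig` objects in 1D transect mode by
default (a ``shape`` override switches to the 2D lattice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .biometrics import Transect, classify, compute_biometrics
from .engine import SimConfig, run
from .params import ModelParams, apply_hypothesis

__all__ = ["ExperimentPreset", "PRESETS", "preset_configs", "run_panel"]

W_LEVELS = tuple(np.round(np.linspace(0.1, 2.0, 6), 6))
GF_LEVELS = tuple(np.round(np.linspace(0.01, 0.05, 5), 6))
ST_COMBINED = (0.1, 0.3, 0.5)
ST_PHYTOTOX = tuple(np.round(np.linspace(0.9, 1.3, 5), 6))

#: The type-1.3 showcase: a fungus shedding abundant, fast-volatilizing
#: phytostimulants in wet soil.
TYPE13_OVERRIDES = {"c_S": 0.8, "k_S": 1.0, "g_N": 0.2, "W": 2.0, "g_F": 0.05}


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    mode: str                                  #: hypothesis mode
    grid: dict[str, tuple[float, ...]]         #: parameter levels, crossed
    overrides: dict[str, float] = field(default_factory=dict)

    def configs(self, base: SimConfig | None = None) -> Iterator[tuple[dict, SimConfig]]:
        """Yield (grid point, concrete config) over the cartesian grid."""
        if base is None:
            base = SimConfig()
        params = apply_hypothesis(base.params, self.mode).replace(**self.overrides)
        names = list(self.grid)
        shapes = [self.grid[n] for n in names]
        mesh = np.meshgrid(*shapes, indexing="ij") if names else []
        points = (
            [dict(zip(names, vals)) for vals in zip(*(m.ravel() for m in mesh))]
            if names
            else [{}]
        )
        for point in points:
            yield point, base.replace(
                params=params.replace(**point), hypothesis_mode=None
            )


PRESETS: dict[str, ExperimentPreset] = {
    "fig4_hydrophobicity": ExperimentPreset(
        "fig4_hydrophobicity", "hydrophobicity",
        {"W": W_LEVELS, "g_F": GF_LEVELS},
    ),
    "fig5_phytotoxicity": ExperimentPreset(
        "fig5_phytotoxicity", "phytotoxicity",
        {"s_T": ST_PHYTOTOX, "g_F": GF_LEVELS},
    ),
    "fig6_combined": ExperimentPreset(
        "fig6_combined", "combined",
        {"s_T": ST_COMBINED, "W": W_LEVELS, "g_F": GF_LEVELS},
    ),
    "type13_demo": ExperimentPreset(
        "type13_demo", "combined", {}, overrides=TYPE13_OVERRIDES
    ),
    "ring_vs_disk": ExperimentPreset(
        "ring_vs_disk", "combined", {"s_I": (1.0, 0.0)},
    ),
}


def preset_configs(name: str, base: SimConfig | None = None):
    try:
        preset = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return preset, list(preset.configs(base))


def run_panel(name: str, base: SimConfig | None = None) -> pd.DataFrame:
    """Run every grid cell of a preset and classify its final transect.

    Returns one row per cell: the varied parameters, the five biometrics and
    the ring-type label. The ``ring_vs_disk`` contrast additionally zeroes
    ``s_F`` alongside ``s_I`` (both self-inhibition channels off in the disk
    arm).
    """
    preset, configs = preset_configs(name, base)
    rows = []
    for point, cfg in configs:
        if preset.name == "ring_vs_disk" and point.get("s_I") == 0.0:
            cfg = cfg.replace(params=cfg.params.replace(s_F=0.0))
        traj = run(cfg)
        x, F, P = traj.final_transect()
        rec = compute_biometrics(Transect(x, F, P, time=traj.times[-1]))
        rows.append({**point, **rec.as_dict(), "type": classify(rec).value})
    return pd.DataFrame(rows)
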