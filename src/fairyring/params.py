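"""Parameter set of the fairy-ring plant–fungus interaction model.

The model couples six densities on a soil lattice — fungal mycelium ``F``,
fungal self-inhibitor ``I``, phytotoxins ``T``, phytostimulants ``S``, plant
biomass ``P`` and soil nutrients ``N`` (all g dm^-2) — through local reaction
terms plus diffusion of ``F`` and ``P``. :class:`ModelParams` carries every
rate constant with its published default; the three hypothesis modes
(hydrophobicity, phytotoxicity, combined) are expressed purely through the
two switch parameters ``a`` (hydrophobic water exclusion) and ``s_T``
(phytotoxin sensitivity of plants).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

__all__ = [
    "ModelParams",
    "PARAM_NAMES",
    "PARAM_RANGES",
    "HYPOTHESIS_MODES",
    "apply_hypothesis",
]


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the six-equation model.

    Units: rates in d^-1; sensitivities and the hydrophobicity coefficient
    ``a`` in dm^2 g^-1 (or dm^2 d^-1 g^-1 where they multiply a density
    twice); diffusivities in dm^2 d^-1; ``k_W``, ``b``, ``c_I``, ``g_N``,
    ``u_N`` and the soil-water input ``W`` are dimensionless as published.

    The defaults reproduce the published reference simulation (combined
    hypothesis, ``W = 1``, ``g_F = 0.05``); the ranged parameters and their
    admissible intervals are listed in :data:`PARAM_RANGES`.
    """

    g_F: float = 0.05    #: fungus growth rate, d^-1, range [0.01, 0.05]
    s_I: float = 1.0     #: sensitivity of fungal growth to the self-inhibitor
    k_W: float = 0.3     #: Michaelis-Menten half-saturation for soil water
    d_F: float = 0.005   #: density-dependent fungus death rate
    s_F: float = 2.0     #: sensitivity of fungus death to the self-inhibitor
    c_I: float = 0.05    #: fraction of dead fungus converted to inhibitor
    k_I: float = 0.001   #: inhibitor degradation rate, d^-1
    l_I: float = 0.001   #: inhibitor leaching rate, d^-1 (scaled by W_bar)
    c_T: float = 0.07    #: phytotoxin production rate per unit fungus, d^-1
    k_T: float = 0.07    #: phytotoxin degradation rate, d^-1
    l_T: float = 0.01    #: phytotoxin leaching rate, d^-1 (scaled by W_bar)
    a: float = 2.0       #: hydrophobicity: water exclusion per unit fungus (0 = off)
    b: float = 9.0       #: base of the water-infiltration power law; must be > 1
    g_P: float = 0.9     #: plant growth rate, dm^2 d^-1 g^-1
    q_P: float = 1.0     #: baseline plant carrying capacity, g dm^-2
    s_T: float = 0.3     #: plant sensitivity to phytotoxins (0 = off)
    c_S: float = 0.07    #: phytostimulant production rate per unit fungus, d^-1
    k_S: float = 0.07    #: phytostimulant degradation rate, d^-1
    g_N: float = 0.08    #: fraction of plant mortality returned as nutrients
    u_N: float = 0.3     #: nutrient uptake coefficient of plants
    l_N: float = 0.1     #: nutrient leaching rate, d^-1 (scaled by W_bar)
    W: float = 1.0       #: soil-water input, dimensionless, range [0.1, 2]
    D_F: float = 0.01    #: fungus diffusivity, dm^2 d^-1
    D_P: float = 0.01    #: plant (vegetative spread) diffusivity, dm^2 d^-1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0):
                raise ValueError(f"parameter {f.name} must be >= 0, got {v!r}")
        if not self.b > 1:
            raise ValueError(
                f"b must be > 1 so that available water stays in [0, 1); got b={self.b}"
            )

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given parameters replaced."""
        unknown = set(changes) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(
                f"unknown parameter(s) {sorted(unknown)}; valid names: {PARAM_NAMES}"
            )
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ModelParams":
        return cls().replace(**dict(mapping))


#: Canonical parameter order (the published table's order).
PARAM_NAMES: tuple[str, ...] = tuple(f.name for f in fields(ModelParams))

#: Published admissible intervals for the ranged parameters. ``s_T`` ranges
#: depend on the hypothesis mode and are given in :data:`HYPOTHESIS_MODES`.
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "g_F": (0.01, 0.05),
    "W": (0.1, 2.0),
}

#: Hypothesis switches: value of ``a`` and admissible ``s_T`` interval
#: (lo, hi, default) for each mode.
HYPOTHESIS_MODES: dict[str, dict[str, object]] = {
    "hydrophobicity": {"a": 2.0, "s_T_range": (0.0, 0.0), "s_T": 0.0},
    "phytotoxicity": {"a": 0.0, "s_T_range": (0.9, 1.3), "s_T": 1.1},
    "combined": {"a": 2.0, "s_T_range": (0.1, 0.5), "s_T": 0.3},
}


def apply_hypothesis(params: ModelParams, mode: str) -> ModelParams:
    """Switch the model between the vegetation-suppression hypotheses.

    ``hydrophobicity`` keeps water exclusion (``a = 2``) and removes
    phytotoxicity (``s_T = 0``); ``phytotoxicity`` removes water exclusion
    (``a = 0``) and sets ``s_T`` to the midpoint of its published
    phytotoxicity-only range [0.9, 1.3]; ``combined`` keeps both (``a = 2``,
    ``s_T = 0.3``, midpoint of [0.1, 0.5]).
    """
    try:
        spec = HYPOTHESIS_MODES[mode]
    except KeyError:
        raise ValueError(
            f"unknown hypothesis mode {mode!r}; expected one of "
            f"{sorted(HYPOTHESIS_MODES)}"
        ) from None
    return params.replace(a=float(spec["a"]), s_T=float(spec["s_T"]))
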