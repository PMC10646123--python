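"""Fairy-ring biometry: turn an (F, P) transect into the five field-measurable
indicators and a ring-type label.

Indicators (all from one radial transect, fungal front travelling toward
increasing x):

* **FB** — fungal biomass: the mycelium peak (g dm^-2).
* **PS** — plant stimulation: peak plant biomass in the stimulated band
  minus the undisturbed steady-state baseline.
* **PI** — plant inhibition: maximum drop of plant biomass below the
  baseline.
* **BZ** — bare zone: total width of the belt where plants are inhibited.
* **RW** — ring width: distance between the fungal and plant biomass peaks
  (undefined when no stimulated band exists).

Ring types follow the classical grassland typology: a dead belt with inner
flourishing vegetation (1), stimulation on both sides of the dead belt (1.1),
a dead belt alone (1.2), like 1.1 but with the outer stimulation stronger
(1.3), stimulation only (2), and no visible effect (3).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import fungus_free_equilibrium
from .params import ModelParams

__all__ = [
    "Transect",
    "Band",
    "BiometricRecord",
    "FRType",
    "baseline",
    "compute_biometrics",
    "classify",
    "read_transect",
    "write_transect",
]

#: Default significance tolerance: a plant-biomass deviation smaller than 2%
#: of the baseline is treated as "no visible effect".
DEFAULT_EPSILON = 0.02

#: Fungal density (g dm^-2) below which soil counts as ahead of the front.
FRONT_THRESHOLD = 1e-3


class FRType(enum.Enum):
    """The six fairy-ring types distinguishable from a biomass transect."""

    TYPE_1 = "1"      # dead belt, flourishing belt behind it
    TYPE_1_1 = "1.1"  # dead belt, stimulation both sides (behind >= ahead)
    TYPE_1_2 = "1.2"  # dead belt only
    TYPE_1_3 = "1.3"  # like 1.1 but the ahead stimulation is stronger
    TYPE_2 = "2"      # stimulation only
    TYPE_3 = "3"      # no visible effect

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Transect:
    """Radial biomass transect: x increasing away from the ring centre."""

    x: np.ndarray
    F: np.ndarray
    P: np.ndarray
    time: float = float("nan")

    def __post_init__(self) -> None:
        x, F, P = (np.asarray(v, float) for v in (self.x, self.F, self.P))
        if not (len(x) == len(F) == len(P)):
            raise ValueError("x, F, P must have equal lengths")
        if len(x) >= 2 and not np.all(np.diff(x) > 0):
            raise ValueError("x must be strictly increasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "P", P)

    @property
    def dx(self) -> float:
        return float(np.median(np.diff(self.x)))


@dataclass(frozen=True)
class Band:
    """One maximal run of significant plant-biomass deviation."""

    kind: str          #: "stimulated" | "inhibited"
    side: str          #: "ahead" | "behind" the fungal peak
    value: float       #: extreme P in the band (peak if stimulated, trough if inhibited)
    extent: float      #: band width, dm
    x_extreme: float   #: location of the extremum, dm


@dataclass(frozen=True)
class BiometricRecord:
    FB: float
    PS: float
    PI: float
    BZ: float
    RW: float                      #: NaN when no stimulated band exists
    baseline: float                #: far-field plant biomass P_inf
    bands: tuple[Band, ...] = ()
    epsilon: float = DEFAULT_EPSILON

    def as_dict(self) -> dict[str, float]:
        return {
            "FB": self.FB, "PS": self.PS, "PI": self.PI,
            "BZ": self.BZ, "RW": self.RW, "baseline": self.baseline,
        }


def baseline(
    transect: Transect,
    front_threshold: float = FRONT_THRESHOLD,
    min_fraction: float = 0.10,
    params: ModelParams | None = None,
) -> float:
    """Undisturbed plant biomass ahead of the fungal front.

    Mean of ``P`` over the trailing ``min_fraction`` of the domain, which
    must lie entirely beyond the fungal front (``F < front_threshold``) —
    otherwise the front has effectively reached the boundary and no clean
    far field exists. When ``params`` is given the empirical value is
    checked against the closed-form fungus-free equilibrium (it must agree
    within 1%).
    """
    F = transect.F
    n = len(F)
    k = max(2, int(math.ceil(min_fraction * n)))
    above = np.nonzero(F >= front_threshold)[0]
    tail_start = int(above.max()) + 1 if len(above) else 0
    if tail_start > n - k:
        raise ValueError(
            "no fungus-free far field: the front occupies the end of the transect"
        )
    p_inf = float(transect.P[n - k:].mean())
    if params is not None:
        p_star, _ = fungus_free_equilibrium(params)
        if p_star > 0 and abs(p_inf - p_star) > 0.01 * p_star:
            raise ValueError(
                f"far-field biomass {p_inf:.4f} disagrees with the closed-form "
                f"equilibrium {p_star:.4f} by more than 1% (transect not at steady state?)"
            )
    return p_inf


def _parabolic_peak_x(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-cell peak location by 3-point parabolic interpolation around the
    grid argmax ``i`` (the grid position at domain edges or flat tops).

    On a 1-dm grid the raw argmax quantizes peak positions; the physical
    peak moves continuously, and distances between peaks (RW) need sub-cell
    resolution to respond to parameter changes smaller than one cell."""
    if i == 0 or i == len(y) - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    offset = 0.5 * (y[i - 1] - y[i + 1]) / denom
    dx = float(x[1] - x[0]) if len(x) > 1 else 1.0
    return float(x[i] + np.clip(offset, -0.5, 0.5) * dx)


def _bands(
    x: np.ndarray, P: np.ndarray, p_inf: float, eps: float, x_fpeak: float
) -> tuple[Band, ...]:
    dx = float(np.median(np.diff(x))) if len(x) > 1 else 1.0
    dev = np.zeros(len(P), dtype=int)
    dev[P > p_inf * (1.0 + eps)] = 1
    dev[P < p_inf * (1.0 - eps)] = -1
    bands: list[Band] = []
    i = 0
    while i < len(dev):
        if dev[i] == 0:
            i += 1
            continue
        j = i
        while j < len(dev) and dev[j] == dev[i]:
            j += 1
        seg = slice(i, j)
        if dev[i] > 0:
            k = i + int(np.argmax(P[seg]))
            kind = "stimulated"
        else:
            k = i + int(np.argmin(P[seg]))
            kind = "inhibited"
        bands.append(
            Band(
                kind=kind,
                side="ahead" if x[k] > x_fpeak else "behind",
                value=float(P[k]),
                extent=float((j - i) * dx),
                x_extreme=float(x[k]),
            )
        )
        i = j
    return tuple(bands)


def compute_biometrics(
    transect: Transect,
    epsilon: float = DEFAULT_EPSILON,
    front_threshold: float = FRONT_THRESHOLD,
    params: ModelParams | None = None,
    baseline_value: float | None = None,
) -> BiometricRecord:
    """Exhaustive scan of one transect for the five biometric indicators.

    No peak-finding heuristics: FB, PS and PI are global extrema of the raw
    arrays, BZ is the total width where ``P < P_inf*(1-epsilon)``, and RW is
    the distance between the global F and P maxima (ties broken toward the
    front, i.e. the largest x; positions refined to sub-cell resolution by
    parabolic interpolation). RW is NaN when no stimulated band exists —
    without a plant peak the fungal-to-plant peak distance is meaningless.
    """
    if not (0.0 < epsilon < 0.2):
        raise ValueError(f"epsilon must lie in (0, 0.2), got {epsilon}")
    x, F, P = transect.x, transect.F, transect.P
    p_inf = (
        float(baseline_value)
        if baseline_value is not None
        else baseline(transect, front_threshold, params=params)
    )
    dx = transect.dx

    # ties broken toward the front (largest x)
    i_fpeak = len(F) - 1 - int(np.argmax(F[::-1]))
    i_ppeak = len(P) - 1 - int(np.argmax(P[::-1]))

    FB = float(F[i_fpeak])
    PS = max(0.0, float(P.max() - p_inf))
    PI = max(0.0, float(p_inf - P.min()))
    BZ = float(np.count_nonzero(P < p_inf * (1.0 - epsilon)) * dx)
    bands = _bands(x, P, p_inf, epsilon, float(x[i_fpeak]))
    has_stim = any(b.kind == "stimulated" for b in bands)
    RW = (
        abs(_parabolic_peak_x(x, F, i_fpeak) - _parabolic_peak_x(x, P, i_ppeak))
        if has_stim
        else float("nan")
    )
    return BiometricRecord(
        FB=FB, PS=PS, PI=PI, BZ=BZ, RW=RW, baseline=p_inf,
        bands=bands, epsilon=epsilon,
    )


def classify(record: BiometricRecord, epsilon: float | None = None) -> FRType:
    """Ring-type decision tree over the significant bands of a record.

    No significant band -> 3; stimulation only -> 2; inhibition only -> 1.2;
    inhibition with stimulation only behind the fungal peak -> 1; stimulation
    also (or only) ahead of it -> 1.1, upgraded to 1.3 when the ahead peak
    exceeds every peak behind.
    """
    if epsilon is None:
        epsilon = record.epsilon
    stim = [b for b in record.bands if b.kind == "stimulated"]
    inhib = [b for b in record.bands if b.kind == "inhibited"]
    if not stim and not inhib:
        return FRType.TYPE_3
    if stim and not inhib:
        return FRType.TYPE_2
    if inhib and not stim:
        return FRType.TYPE_1_2
    ahead = [b.value for b in stim if b.side == "ahead"]
    behind = [b.value for b in stim if b.side == "behind"]
    if not ahead:
        return FRType.TYPE_1
    if behind and max(ahead) <= max(behind):
        return FRType.TYPE_1_1
    if behind:
        return FRType.TYPE_1_3
    return FRType.TYPE_1_1


def read_transect(path) -> Transect:
    """Read a headered delimited table with columns x, F, P (comma, tab or
    whitespace separated)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"x", "F", "P"} - set(df.columns)
    if missing:
        raise ValueError(f"transect table lacks column(s) {sorted(missing)}")
    time = float(df["time"].iloc[0]) if "time" in df.columns else float("nan")
    return Transect(df["x"].to_numpy(), df["F"].to_numpy(), df["P"].to_numpy(), time=time)


def write_transect(transect: Transect, path) -> None:
    df = pd.DataFrame({"x": transect.x, "F": transect.F, "P": transect.P})
    if np.isfinite(transect.time):
        df["time"] = transect.time
    df.to_csv(path, index=False)
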