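"""Local dynamics of the fairy-ring model: reaction terms, the available-water
function, the zero-flux Laplacian, and closed-form/root-found equilibria.

Everything here is a pure function over numpy arrays (or scalars); the time
loop lives in :mod:`fairyring.engine`.

Model sketch
------------
Fungal mycelium ``F`` grows on soil water ``W``, limited and killed by its own
accumulated self-inhibitor ``I`` (the mechanism that turns a disk into a
ring). A dense mycelial mat is hydrophobic: the fraction of soil water that
actually reaches plants and drives leaching, ``W_bar``, decays with fungal
density (``available_water``). The fungus releases phytotoxins ``T`` (killing
plants) and phytostimulants ``S`` (raising the plant carrying capacity);
dying plants return nutrients ``N`` to the soil. Plants ``P`` grow
logistically toward the water-limited carrying capacity
``W_bar * (q_P + S + N)``.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import optimize

from .params import ModelParams

__all__ = [
    "available_water",
    "fungus_reaction",
    "inhibitor_reaction",
    "toxin_reaction",
    "stimulant_reaction",
    "plant_reaction",
    "nutrient_reaction",
    "reaction_rates",
    "laplacian",
    "homogeneous_fixed_point",
    "fungus_free_equilibrium",
]


def available_water(F, params: ModelParams):
    """Water fraction available to plants and leaching under a mycelial mat.

    ``W_bar = 1 - b**(a*F - W)`` where ``a*F < W`` and 0 otherwise, so the
    result lies in ``[0, 1)``: bare soil (``F = 0``) passes ``1 - b**(-W)``
    of its water to plants, and a mat dense enough that ``a*F >= W`` blocks
    infiltration completely.
    """
    F = np.asarray(F, dtype=float)
    p = params
    exponent = p.a * F - p.W
    with np.errstate(over="ignore"):
        wbar = np.where(exponent < 0.0, 1.0 - p.b ** np.minimum(exponent, 0.0), 0.0)
    return wbar


def fungus_reaction(F, I, params: ModelParams):
    """Net local fungal growth rate.

    Growth is Michaelis–Menten in the soil-water input ``W`` (the fungus taps
    water at the mat border, so the raw input and not ``W_bar`` appears) and
    is shut down linearly by the self-inhibitor; losses are quadratic
    self-thinning plus inhibitor-induced mortality.
    """
    p = params
    growth = p.g_F * F * (1.0 - p.s_I * I) * (p.W / (p.W + p.k_W))
    return growth - p.d_F * F**2 - p.s_F * F * I


def inhibitor_reaction(F, I, W_bar, params: ModelParams):
    """Self-inhibitor budget: a fraction ``c_I`` of the fungal mortality flux
    accumulates in the soil; losses are first-order decay plus leaching
    proportional to the available water."""
    p = params
    return p.c_I * (p.d_F * F**2 + p.s_F * F * I) - p.k_I * I - p.l_I * I * W_bar


def toxin_reaction(F, T, W_bar, params: ModelParams):
    """Phytotoxin budget: produced at rate ``c_T`` per unit fungus, degraded
    at ``k_T`` and leached at ``l_T * W_bar``."""
    p = params
    return p.c_T * F - p.k_T * T - p.l_T * T * W_bar


def stimulant_reaction(F, S, params: ModelParams):
    """Phytostimulant budget: produced at ``c_S`` per unit fungus and lost by
    volatilization/degradation at ``k_S``; no leaching term."""
    p = params
    return p.c_S * F - p.k_S * S


def plant_reaction(P, W_bar, S, N, T, params: ModelParams):
    """Net local plant growth rate: logistic toward the carrying capacity
    ``W_bar * (q_P + S + N)`` minus phytotoxin-induced mortality."""
    p = params
    return p.g_P * P * (W_bar * (p.q_P + S + N) - P) - p.s_T * T * P


def nutrient_reaction(P, N, T, W_bar, params: ModelParams):
    """Soil-nutrient budget, entirely water-gated: a fraction ``g_N`` of the
    plant mortality flux (self-thinning ``g_P*P**2`` plus toxin kill) is
    mineralized; plants take nutrients up at ``u_N * g_P * P`` and the rest
    leaches at ``l_N``."""
    p = params
    release = p.g_N * (p.g_P * P**2 + p.s_T * P * T) * W_bar
    uptake = p.u_N * p.g_P * W_bar * P * N
    return release - uptake - p.l_N * N * W_bar


class Rates(NamedTuple):
    F: np.ndarray
    I: np.ndarray
    T: np.ndarray
    S: np.ndarray
    P: np.ndarray
    N: np.ndarray


def reaction_rates(F, I, T, S, P, N, params: ModelParams, W_bar=None) -> Rates:
    """All six non-diffusive rates from one state snapshot.

    ``W_bar`` is computed once from ``F`` (frozen-coefficient evaluation: all
    rates see the same start-of-step water field) unless supplied.
    """
    if W_bar is None:
        W_bar = available_water(F, params)
    return Rates(
        F=fungus_reaction(F, I, params),
        I=inhibitor_reaction(F, I, W_bar, params),
        T=toxin_reaction(F, T, W_bar, params),
        S=stimulant_reaction(F, S, params),
        P=plant_reaction(P, W_bar, S, N, T, params),
        N=nutrient_reaction(P, N, T, W_bar, params),
    )


def laplacian(field, dx: float, out=None):
    """Discrete Laplacian with zero-flux (Neumann) boundaries.

    Central 3-point (1D) or 5-point (2D) stencil divided by ``dx**2``;
    boundaries are handled by mirroring ghost cells, so the operator
    conserves mass: the domain sum of the result is zero to round-off.
    """
    f = np.asarray(field, dtype=float)
    if dx <= 0:
        raise ValueError(f"dx must be positive, got {dx}")
    if any(n < 3 for n in f.shape):
        raise ValueError(f"grid must have >= 3 cells per dimension, got shape {f.shape}")
    if f.ndim == 1:
        p = np.pad(f, 1, mode="edge")
        lap = p[:-2] - 2.0 * f + p[2:]
    elif f.ndim == 2:
        p = np.pad(f, 1, mode="edge")
        lap = p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * f
    else:
        raise ValueError(f"only 1D and 2D grids are supported, got ndim={f.ndim}")
    lap /= dx * dx
    if out is not None:
        out[...] = lap
        return out
    return lap


def _reaction_vector(x: np.ndarray, params: ModelParams) -> np.ndarray:
    F, I, T, S, P, N = x
    r = reaction_rates(F, I, T, S, P, N, params)
    return np.array([float(r.F), float(r.I), float(r.T), float(r.S), float(r.P), float(r.N)])


def homogeneous_fixed_point(
    params: ModelParams,
    guess=(0.02, 0.02, 0.02, 0.02, 1.0, 0.2),
    tol: float = 1e-12,
) -> np.ndarray:
    """Non-trivial spatially homogeneous equilibrium ``(F, I, T, S, P, N)``.

    Found by a generic root-finder on the six reaction equations with
    diffusion removed (a uniform field makes the diffusion terms vanish, so
    this is also a stationary state of the full spatial model). Raises
    ``RuntimeError`` if the solver does not converge to a non-negative root.
    """
    sol = optimize.root(_reaction_vector, np.asarray(guess, float), args=(params,), tol=tol)
    x = sol.x
    if not sol.success or np.any(x < -1e-9):
        raise RuntimeError(f"root-finder failed to locate a non-negative equilibrium: {sol.message}")
    return np.clip(x, 0.0, None)


def fungus_free_equilibrium(params: ModelParams) -> tuple[float, float]:
    """Plant/nutrient equilibrium ``(P*, N*)`` of fungus-free soil.

    With ``F = I = T = S = 0`` the water fraction is the constant
    ``W_bar0 = 1 - b**(-W)`` and the nutrient balance pins
    ``N(P) = g_N*g_P*P**2 / (u_N*g_P*P + l_N)``; ``P*`` is the root of
    ``P = W_bar0 * (q_P + N(P))`` (found by Brent bracketing). Because
    plant self-thinning keeps mineralizing nutrients, ``N* > 0`` and ``P*``
    sits above the nutrient-free logistic level ``W_bar0 * q_P`` (to which it
    collapses exactly when ``g_N = 0``). This is the far-field baseline that
    a vegetated transect relaxes to ahead of the fungal front.
    """
    p = params
    w0 = float(available_water(0.0, p))
    if w0 == 0.0 or p.g_P == 0.0:
        return 0.0, 0.0

    def nutrient(P: float) -> float:
        denom = p.u_N * p.g_P * P + p.l_N
        if denom == 0.0:
            return 0.0
        return p.g_N * p.g_P * P * P / denom

    def f(P: float) -> float:
        return P - w0 * (p.q_P + nutrient(P))

    hi = max(10.0 * w0 * p.q_P, 1.0)
    while f(hi) < 0 and hi < 1e12:
        hi *= 10.0
    P_star = optimize.brentq(f, 1e-12, hi, xtol=1e-14, rtol=8.9e-16)
    return float(P_star), float(nutrient(P_star))
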