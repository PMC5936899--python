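"""Pure evaluation of the model's constitutive functions and drift field.

The climate side is a zero-dimensional energy balance

    C_T dT/dt = (1 - alpha(T, A)) Q0 - R0(T),

where the planetary albedo ``alpha`` mixes ocean albedo (a ramp in T through
the ice-albedo feedback) with land albedo (a convex combination of vegetated
and bare ground), and the outgoing flux ``R0`` is linear in T.  Vegetation
cover follows the logistic law

    dA/dt = beta(T) A (1 - A) - gamma A,

with a parabolic growth rate beta(T) = max(0, 1 - k (T - T_opt)^2).

All functions accept scalars or numpy arrays in ``T``/``A`` and broadcast.
"""

from __future__ import annotations

import numpy as np

from .params import ClimateParams, State

__all__ = [
    "ocean_albedo",
    "planetary_albedo",
    "outgoing_radiation",
    "growth_rate",
    "drift",
    "jacobian",
]


def ocean_albedo(T, params: ClimateParams):
    """Ocean albedo as a ramp function of temperature.

    Equal to ``alpha_max`` for T <= T_alpha_l (ice-covered ocean),
    ``alpha_min`` for T > T_alpha_u (ice-free), and linearly interpolated in
    between; continuous at both breakpoints.
    """
    T = np.asarray(T, dtype=float)
    slope = (params.alpha_min - params.alpha_max) / (params.T_alpha_u - params.T_alpha_l)
    ramp = np.clip(T - params.T_alpha_l, 0.0, params.T_alpha_u - params.T_alpha_l)
    out = params.alpha_max + slope * ramp
    return out if out.shape else float(out)


def planetary_albedo(T, A, params: ClimateParams):
    """Planetary albedo: area-weighted mix of ocean and land albedo,

    alpha(T, A) = (1 - p) alpha_o(T) + p (alpha_v A + alpha_g (1 - A)).

    Affine and decreasing in A (vegetation is darker than bare ground).
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0) or np.any(A > 1):
        raise ValueError("vegetation fraction A must lie in [0, 1]")
    land = params.alpha_g + (params.alpha_v - params.alpha_g) * A
    out = (1.0 - params.p) * np.asarray(ocean_albedo(T, params)) + params.p * land
    return out if out.shape else float(out)


def outgoing_radiation(T, params: ClimateParams):
    """Outgoing long-wave flux R0(T) = B0 + B1 (T - T_opt), W m^-2."""
    out = params.B0 + params.B1 * (np.asarray(T, dtype=float) - params.T_opt)
    return out if out.shape else float(out)


def growth_rate(T, params: ClimateParams):
    """Parabolic vegetation growth rate beta(T) = max(0, 1 - k (T - T_opt)^2).

    Nonnegative, symmetric about T_opt with maximum 1 there, and zero outside
    |T - T_opt| >= sqrt(1/k).
    """
    T = np.asarray(T, dtype=float)
    out = np.maximum(0.0, 1.0 - params.k * (T - params.T_opt) ** 2)
    return out if out.shape else float(out)


def drift(state, params: ClimateParams):
    """Deterministic drift field (dT/dt in K yr^-1, dA/dt in yr^-1).

    ``state`` may be a :class:`State` or a pair of broadcastable arrays.
    dA/dt vanishes identically on the invariant line A = 0.
    """
    T, A = state
    T = np.asarray(T, dtype=float)
    A = np.asarray(A, dtype=float)
    dT = ((1.0 - planetary_albedo(T, A, params)) * params.Q0
          - outgoing_radiation(T, params)) / params.C_T
    # association beta*(A*(1-A)) matches the simulation kernels bit-for-bit
    dA = growth_rate(T, params) * (A * (1.0 - A)) - params.gamma * A
    if np.ndim(dT) == 0 and np.ndim(dA) == 0:
        return float(dT), float(dA)
    return dT, dA


def jacobian(state, params: ClimateParams, *, seam_shift: float = 1e-9) -> np.ndarray:
    """Analytic 2x2 Jacobian of the drift at ``state`` (units yr^-1).

    The drift is only piecewise-smooth: the ocean-albedo ramp has kinks at the
    two ramp temperatures and the growth rate at the edges of its support.
    Exactly on a seam the temperature is nudged by ``seam_shift`` kelvin toward
    the segment the state sits in, i.e. a one-sided derivative is taken; the
    seams are measure-zero and no default equilibrium lies on one.
    """
    T, A = float(state[0]), float(state[1])
    for seam in (params.T_alpha_l, params.T_alpha_u,
                 params.T_opt - params.beta_support_halfwidth,
                 params.T_opt + params.beta_support_halfwidth):
        if T == seam:
            T += seam_shift
            break

    # d alpha_o / dT on the current segment
    if params.T_alpha_l < T < params.T_alpha_u:
        dao = (params.alpha_min - params.alpha_max) / (params.T_alpha_u - params.T_alpha_l)
    else:
        dao = 0.0
    # d beta / dT on the current segment
    if abs(T - params.T_opt) < params.beta_support_halfwidth:
        dbeta = -2.0 * params.k * (T - params.T_opt)
    else:
        dbeta = 0.0

    beta = float(growth_rate(T, params))
    dFdT = (-params.Q0 * (1.0 - params.p) * dao - params.B1) / params.C_T
    dFdA = -params.Q0 * params.p * (params.alpha_v - params.alpha_g) / params.C_T
    dGdT = dbeta * A * (1.0 - A)
    dGdA = beta * (1.0 - 2.0 * A) - params.gamma
    return np.array([[dFdT, dFdA], [dGdT, dGdA]])
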