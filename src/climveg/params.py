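"""Parameter containers and phase-space state for the climate-vegetation model.

The model couples a zero-dimensional energy-balance equation for the global
mean temperature ``T`` (kelvin) with a logistic law for the vegetated land
fraction ``A``.  All physical constants live in :class:`ClimateParams`;
the default values are the standard parameter set for this model
(Rombouts-Ghil-type energy balance with ice-albedo ramp and parabolic
vegetation growth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import NamedTuple


class State(NamedTuple):
    """A phase point: global mean temperature ``T`` (K) and vegetated land
    fraction ``A`` (dimensionless, in [0, 1])."""

    T: float
    A: float


def validate_state(state: State) -> State:
    T, A = float(state[0]), float(state[1])
    if not (math.isfinite(T) and T > 0):
        raise ValueError(f"temperature must be finite and positive, got {T!r}")
    if not (math.isfinite(A) and 0.0 <= A <= 1.0):
        raise ValueError(f"vegetation fraction must lie in [0, 1], got {A!r}")
    return State(T, A)


@dataclass(frozen=True)
class ClimateParams:
    """Physical constants of the climate-vegetation feedback model.

    Parameters
    ----------
    C_T : float
        Effective heat capacity of the climate system (W yr K^-1 m^-2).
    Q0 : float
        Incoming solar flux (W m^-2).
    p : float
        Fraction of the planet that is land, in [0, 1].
    alpha_v, alpha_g : float
        Albedo of vegetated and bare ground; vegetation is darker
        (``alpha_v < alpha_g``).
    alpha_max, alpha_min : float
        Albedo of ice-covered and ice-free ocean.
    T_alpha_l, T_alpha_u : float
        Ramp temperatures (K): ocean fully ice-covered at or below the lower
        one, ice-free above the upper one, linear in between.
    B0, B1 : float
        Outgoing-radiation constant (W m^-2) and slope (W K^-1 m^-2).
    T_opt : float
        Optimal vegetation growth temperature (K); also the reference
        temperature of the outgoing-radiation linearization.
    k : float
        Width parameter of the parabolic growth curve (yr^-1 K^-2).
    gamma : float
        Vegetation death rate (yr^-1).
    """

    C_T: float = 500.0
    Q0: float = 342.5
    p: float = 0.3
    alpha_v: float = 0.1
    alpha_g: float = 0.4
    alpha_max: float = 0.85
    alpha_min: float = 0.25
    T_alpha_l: float = 263.0
    T_alpha_u: float = 300.0
    B0: float = 200.0
    B1: float = 2.5
    T_opt: float = 283.0
    k: float = 0.004
    gamma: float = 0.1

    def __post_init__(self) -> None:
        if not self.alpha_v < self.alpha_g:
            raise ValueError(
                "alpha_v < alpha_g required: vegetation absorbs more energy "
                f"than bare ground (got alpha_v={self.alpha_v}, alpha_g={self.alpha_g})"
            )
        if not self.alpha_min < self.alpha_max:
            raise ValueError("alpha_min < alpha_max required")
        if not self.T_alpha_l < self.T_alpha_u:
            raise ValueError("T_alpha_l < T_alpha_u required")
        for name in ("alpha_v", "alpha_g", "alpha_max", "alpha_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        for name in ("C_T", "Q0", "B1", "k", "gamma"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v}")

    def with_gamma(self, gamma: float) -> "ClimateParams":
        """Return a copy with a different vegetation death rate."""
        return replace(self, gamma=gamma)

    @property
    def beta_support_halfwidth(self) -> float:
        """Half-width sqrt(1/k) of the temperature interval with positive
        vegetation growth rate."""
        return math.sqrt(1.0 / self.k)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Names of the flat config keys, in canonical order.
PARAM_KEYS: tuple[str, ...] = tuple(f.name for f in fields(ClimateParams))


@dataclass(frozen=True)
class NoiseConfig:
    """Settings for a stochastic (Euler-Maruyama) run.

    epsilon is the intensity of the Gaussian white noise perturbing the
    vegetation growth rate; its units are those of the growth rate, with the
    sqrt(yr) scaling absorbed into the Wiener increment.
    """

    epsilon: float = 0.0
    seed: int = 0
    dt: float = 0.01
    t_max: float = 5000.0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.t_max >= self.dt:
            raise ValueError("t_max must be >= dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt))

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "seed": self.seed,
            "dt": self.dt,
            "t_max": self.t_max,
        }
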