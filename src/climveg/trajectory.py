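"""Time-indexed trajectories of the climate-vegetation system."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import State

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """A uniformly sampled trajectory with provenance metadata.

    Attributes
    ----------
    times : ndarray
        Strictly increasing sample times (yr), uniform spacing.
    T : ndarray
        Global mean temperature at each sample (K).
    A : ndarray
        Vegetated land fraction at each sample, in [0, 1].
    meta : dict
        Provenance: model parameters, integration settings, and for
        stochastic runs the noise intensity and seed.
    """

    times: np.ndarray
    T: np.ndarray
    A: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if not (self.times.shape == self.T.shape == self.A.shape):
            raise ValueError("times, T and A must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.A < 0) or np.any(self.A > 1):
            raise ValueError("vegetation fraction outside [0, 1] in trajectory")

    def __len__(self) -> int:
        return self.times.size

    @property
    def initial_state(self) -> State:
        return State(float(self.T[0]), float(self.A[0]))

    @property
    def final_state(self) -> State:
        return State(float(self.T[-1]), float(self.A[-1]))

    def state_at(self, i: int) -> State:
        return State(float(self.T[i]), float(self.A[i]))

    def after(self, t0: float) -> "Trajectory":
        """Sub-trajectory with times >= t0 (e.g. to discard a transient)."""
        m = self.times >= t0
        return Trajectory(self.times[m], self.T[m], self.A[m], dict(self.meta))
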