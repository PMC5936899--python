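"""Euler-Maruyama simulation of the stochastically forced system.

The noise perturbs only the vegetation growth rate: beta(T) is replaced by
beta(T) + eps*xi(t) with xi standard Gaussian white noise, so the vegetation
equation becomes the Ito SDE

    dA = [beta(T) A (1 - A) - gamma A] dt + eps A (1 - A) dW.

The temperature equation carries no noise and is advanced with plain Euler
inside the same step, sharing the time grid (the Euler-Maruyama scheme is
first-order overall anyway).  The multiplicative factor A(1 - A) vanishes at
A = 0 and A = 1, so those lines are invariant for the exact SDE; after each
step A is clamped to [0, 1] to keep discretization excursions inside the
physical range without biasing dynamics near the edges.

Reproducibility contract: run *i* of an ensemble consumes the stream of
``numpy.random.Generator(PCG64(base_seed + i))`` in a fixed chunked order, so
a single run with that seed is bit-identical to member *i* of any batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ClimateParams, NoiseConfig, State
from .trajectory import Trajectory

__all__ = ["simulate_em", "simulate_ensemble", "integrate_euler",
           "first_passage_ensemble", "sample_ensemble", "EnsembleSamples"]

#: Steps per noise chunk; part of the reproducibility contract (the Gaussian
#: stream is drawn ``_CHUNK`` deviates at a time per run).
_CHUNK = 4096


def _rngs(base_seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(base_seed + i)) for i in range(n)]


@dataclass
class EnsembleSamples:
    """Thinned ensemble output: times (n_samples,), T and A (n_runs, n_samples),
    first-passage step index per run (-1 if no passage)."""

    times: np.ndarray
    T: np.ndarray
    A: np.ndarray
    passage_step: np.ndarray
    dt: float
    clamp_fraction: float

    def passage_times(self) -> np.ndarray:
        """First-passage times in years, NaN where no passage occurred."""
        t = self.passage_step * self.dt
        return np.where(self.passage_step >= 0, t, np.nan)


def _evolve(T: np.ndarray, A: np.ndarray, p: ClimateParams, eps: float,
            dt: float, n_steps: int, rngs, *, threshold: float | None = None,
            stride: int = 0, stop_when_all_passed: bool = False):
    """Vectorized EM kernel over an ensemble (arrays T, A modified in place).

    Returns (passage_step, times, sampled_T, sampled_A, clamp_fraction).
    ``stride`` > 0 records every stride-th step (plus step 0);
    ``threshold`` enables first-passage tracking of T < threshold.
    """
    n = T.size
    sqrt_dt = math.sqrt(dt)
    slope = (p.alpha_min - p.alpha_max) / (p.T_alpha_u - p.T_alpha_l)
    span = p.T_alpha_u - p.T_alpha_l
    pocean, pland = 1.0 - p.p, p.p
    dva = p.alpha_v - p.alpha_g

    passage = np.full(n, -1, dtype=np.int64)
    if threshold is not None:
        passage[T < threshold] = 0
    rec_t, rec_T, rec_A = [], [], []
    if stride:
        rec_t.append(0.0)
        rec_T.append(T.copy())
        rec_A.append(A.copy())
    n_clamped = 0
    step = 0
    while step < n_steps:
        m = min(_CHUNK, n_steps - step)
        if eps > 0.0:
            Z = np.empty((n, m))
            for i, rg in enumerate(rngs):
                Z[i] = rg.standard_normal(m)
        for j in range(m):
            ao = p.alpha_max + slope * np.clip(T - p.T_alpha_l, 0.0, span)
            alpha = pocean * ao + pland * (p.alpha_g + dva * A)
            dT = ((1.0 - alpha) * p.Q0 - (p.B0 + p.B1 * (T - p.T_opt))) / p.C_T
            beta = np.maximum(0.0, 1.0 - p.k * (T - p.T_opt) ** 2)
            AA = A * (1.0 - A)
            dA = beta * AA - p.gamma * A
            T += dt * dT
            if eps > 0.0:
                A += dt * dA + (eps * sqrt_dt) * AA * Z[:, j]
            else:
                A += dt * dA
            low, high = A < 0.0, A > 1.0
            n_clamped += int(np.count_nonzero(low) + np.count_nonzero(high))
            np.clip(A, 0.0, 1.0, out=A)
            s = step + j + 1
            if threshold is not None:
                newly = (passage < 0) & (T < threshold)
                if newly.any():
                    passage[newly] = s
            if stride and s % stride == 0:
                rec_t.append(s * dt)
                rec_T.append(T.copy())
                rec_A.append(A.copy())
        if not np.all(np.isfinite(T)):
            bad = int(np.argmin(np.isfinite(T)))
            raise FloatingPointError(
                f"non-finite temperature in run {bad} near step {step + m}")
        step += m
        if stop_when_all_passed and threshold is not None and np.all(passage >= 0):
            break
    clamp_fraction = n_clamped / (n * max(step, 1))
    times = np.array(rec_t)
    sT = np.array(rec_T).T if rec_T else np.empty((n, 0))
    sA = np.array(rec_A).T if rec_A else np.empty((n, 0))
    return passage, times, sT, sA, clamp_fraction


def simulate_em(state0: State, params: ClimateParams, noise: NoiseConfig,
                record_stride: int = 1) -> Trajectory:
    """Single Euler-Maruyama trajectory.

    With ``noise.epsilon == 0`` this is exactly the deterministic Euler
    solution on the same grid.  Identical ``(seed, dt, t_max, epsilon)``
    always reproduce the trajectory bit-for-bit.
    """
    T = np.array([float(state0[0])])
    A = np.array([float(state0[1])])
    rngs = _rngs(noise.seed, 1)
    _, times, sT, sA, clamp = _evolve(
        T, A, params, noise.epsilon, noise.dt, noise.n_steps, rngs,
        stride=record_stride)
    meta = {"params": params.to_dict(), "scheme": "euler-maruyama",
            "record_stride": record_stride, "clamp_fraction": clamp,
            **noise.to_dict()}
    return Trajectory(times, sT[0], sA[0], meta)


def integrate_euler(state0: State, params: ClimateParams, t_max: float,
                    dt: float = 0.01, record_stride: int = 1) -> Trajectory:
    """Deterministic Euler reference on the EM grid (the eps = 0 limit)."""
    return simulate_em(state0, params,
                       NoiseConfig(epsilon=0.0, seed=0, dt=dt, t_max=t_max),
                       record_stride=record_stride)


def simulate_ensemble(state0: State, params: ClimateParams, noise: NoiseConfig,
                      n_runs: int, record_stride: int = 1) -> list[Trajectory]:
    """``n_runs`` independent EM trajectories; run i uses seed ``noise.seed + i``.

    Member i is bit-identical to ``simulate_em`` with that seed, independent
    of the batch it is computed in.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    T = np.full(n_runs, float(state0[0]))
    A = np.full(n_runs, float(state0[1]))
    rngs = _rngs(noise.seed, n_runs)
    _, times, sT, sA, clamp = _evolve(
        T, A, params, noise.epsilon, noise.dt, noise.n_steps, rngs,
        stride=record_stride)
    out = []
    for i in range(n_runs):
        meta = {"params": params.to_dict(), "scheme": "euler-maruyama",
                "record_stride": record_stride, "clamp_fraction": clamp,
                **noise.to_dict()}
        meta["seed"] = noise.seed + i
        out.append(Trajectory(times, sT[i], sA[i], meta))
    return out


def first_passage_ensemble(state0: State, params: ClimateParams,
                           noise: NoiseConfig, n_runs: int,
                           T_threshold: float = 260.0) -> np.ndarray:
    """First-passage times (yr) below ``T_threshold`` for an ensemble.

    Vectorized over runs; stops early once every member has crossed.  Returns
    an array of length ``n_runs`` with NaN for runs that never cross within
    the horizon.
    """
    T = np.full(n_runs, float(state0[0]))
    A = np.full(n_runs, float(state0[1]))
    rngs = _rngs(noise.seed, n_runs)
    passage, *_ = _evolve(T, A, params, noise.epsilon, noise.dt, noise.n_steps,
                          rngs, threshold=T_threshold, stop_when_all_passed=True)
    t = passage * noise.dt
    return np.where(passage >= 0, t, np.nan)


def sample_ensemble(state0: State, params: ClimateParams, noise: NoiseConfig,
                    n_runs: int, record_stride: int = 10,
                    T_threshold: float = 260.0) -> EnsembleSamples:
    """Thinned ensemble samples plus per-run first-passage bookkeeping.

    Used by the density/shift statistics, which need pooled temperature
    samples and the pre-transition segment boundaries.
    """
    T = np.full(n_runs, float(state0[0]))
    A = np.full(n_runs, float(state0[1]))
    rngs = _rngs(noise.seed, n_runs)
    passage, times, sT, sA, clamp = _evolve(
        T, A, params, noise.epsilon, noise.dt, noise.n_steps, rngs,
        threshold=T_threshold, stride=record_stride)
    return EnsembleSamples(times=times, T=sT, A=sA, passage_step=passage,
                           dt=noise.dt, clamp_fraction=clamp)
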