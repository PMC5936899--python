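"""Deterministic dynamics: equilibria, stability, limit cycle, separatrix.

For the default parameter set the system is bistable: a cold "snowball"
equilibrium (ice-covered ocean, no vegetation) coexists with a warm state
(a stable limit cycle at small vegetation death rate gamma, or a stable focus
at larger gamma after a supercritical Andronov-Hopf bifurcation).  The basins
are divided by the stable manifold (separatrix) of a saddle equilibrium.

Equilibria are found by one-dimensional root searches on the two nullcline
branches: the vegetation-free line A = 0, and the interior branch obtained by
eliminating A via A(T) = 1 - gamma/beta(T) wherever beta(T) > gamma.  Each
branch residual (absorbed minus outgoing flux) is only piecewise smooth --
the ocean-albedo ramp has kinks at the two ramp temperatures and the growth
rate at the edges of its support -- so brackets are scanned per continuity
segment before refinement with Brent's method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .model import drift, growth_rate, jacobian, ocean_albedo, outgoing_radiation
from .params import ClimateParams, State
from .trajectory import Trajectory

__all__ = [
    "Equilibrium",
    "CycleSummary",
    "ColdBasinEscape",
    "integrate_ode",
    "find_equilibria",
    "warm_equilibrium",
    "detect_limit_cycle",
    "scan_hopf",
    "refine_hopf",
    "compute_separatrix",
    "basin_of",
    "basin_labels",
    "warm_region",
]

#: Temperature box (K) in which equilibria are sought and outside which
#: separatrix integration stops.
T_BOX = (230.0, 310.0)


class ColdBasinEscape(RuntimeError):
    """Raised when a trajectory expected to stay on the warm attractor
    escapes to the cold (snowball) basin."""


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point with its linearization.

    ``branch`` is ``"vegetation-free"`` (A = 0) or ``"interior"``;
    ``stability`` is one of stable-node, stable-focus, unstable-focus,
    unstable-node, saddle.
    """

    state: State
    branch: str
    eigenvalues: tuple[complex, complex]
    stability: str

    @property
    def is_stable(self) -> bool:
        return self.stability.startswith("stable")

    @property
    def max_real_part(self) -> float:
        return max(ev.real for ev in self.eigenvalues)

    def to_dict(self) -> dict:
        (l1, l2) = self.eigenvalues
        return {
            "branch": self.branch,
            "T": self.state.T,
            "A": self.state.A,
            "eig_re": [l1.real, l2.real],
            "eig_im": [l1.imag, l2.imag],
            "stability": self.stability,
        }


@dataclass(frozen=True)
class CycleSummary:
    """Summary of a detected stable limit cycle."""

    period: float          # yr
    T_range: tuple[float, float]   # K
    A_range: tuple[float, float]


# ----------------------------------------------------------------------
# integration

def _scalar_drift(p: ClimateParams) -> Callable[[float, float], tuple[float, float]]:
    """Closure evaluating the drift with plain floats (hot loop helper)."""
    q, ct, b0, b1 = p.Q0, p.C_T, p.B0, p.B1
    topt, k, gamma = p.T_opt, p.k, p.gamma
    tl, span = p.T_alpha_l, p.T_alpha_u - p.T_alpha_l
    amax, slope = p.alpha_max, (p.alpha_min - p.alpha_max) / (p.T_alpha_u - p.T_alpha_l)
    pland, pocean = p.p, 1.0 - p.p
    ag, dva = p.alpha_g, p.alpha_v - p.alpha_g

    def f(T: float, A: float) -> tuple[float, float]:
        x = T - tl
        if x <= 0.0:
            ao = amax
        elif x >= span:
            ao = amax + slope * span
        else:
            ao = amax + slope * x
        alpha = pocean * ao + pland * (ag + dva * A)
        dT = ((1.0 - alpha) * q - (b0 + b1 * (T - topt))) / ct
        d = T - topt
        beta = 1.0 - k * d * d
        if beta < 0.0:
            beta = 0.0
        return dT, beta * (A * (1.0 - A)) - gamma * A

    return f


def integrate_ode(state0: State, params: ClimateParams, t_max: float,
                  dt: float = 0.01, record_stride: int = 1) -> Trajectory:
    """Integrate the deterministic system with fixed-step classical RK4.

    A is clamped to [0, 1] after each step; the clamp is expected to be
    inactive except for machine-precision excursions at the invariant edges.
    ``record_stride`` thins storage (every n-th step is kept; the step size
    itself is always ``dt``).

    Raises ``FloatingPointError`` if the state becomes non-finite.
    """
    if dt <= 0 or t_max < dt:
        raise ValueError("require dt > 0 and t_max >= dt")
    f = _scalar_drift(params)
    n = int(round(t_max / dt))
    T, A = float(state0[0]), float(state0[1])
    n_rec = n // record_stride + 1
    out_T = np.empty(n_rec)
    out_A = np.empty(n_rec)
    out_T[0], out_A[0] = T, A
    h2, h6 = dt / 2.0, dt / 6.0
    j = 1
    for i in range(1, n + 1):
        k1t, k1a = f(T, A)
        k2t, k2a = f(T + h2 * k1t, A + h2 * k1a)
        k3t, k3a = f(T + h2 * k2t, A + h2 * k2a)
        k4t, k4a = f(T + dt * k3t, A + dt * k3a)
        T += h6 * (k1t + 2.0 * (k2t + k3t) + k4t)
        A += h6 * (k1a + 2.0 * (k2a + k3a) + k4a)
        if A < 0.0:
            A = 0.0
        elif A > 1.0:
            A = 1.0
        if not (-1e6 < T < 1e6):
            raise FloatingPointError(f"non-finite/divergent state at step {i} (t={i * dt:g} yr)")
        if i % record_stride == 0:
            out_T[j], out_A[j] = T, A
            j += 1
    times = np.arange(n_rec) * (dt * record_stride)
    meta = {"params": params.to_dict(), "dt": dt, "t_max": t_max,
            "record_stride": record_stride, "scheme": "rk4"}
    return Trajectory(times[:j], out_T[:j], out_A[:j], meta)


# ----------------------------------------------------------------------
# equilibria

def _classify(eigs: np.ndarray) -> str:
    l1, l2 = eigs
    if abs(l1.imag) > 1e-12 or abs(l2.imag) > 1e-12:
        return "stable-focus" if l1.real < 0 else "unstable-focus"
    r1, r2 = l1.real, l2.real
    if r1 * r2 < 0:
        return "saddle"
    return "stable-node" if max(r1, r2) < 0 else "unstable-node"


def _segment_roots(g: Callable[[float], float], lo: float, hi: float,
                   n_scan: int) -> list[float]:
    """All sign-change roots of g on [lo, hi] via scan + Brent refinement."""
    if hi - lo < 1e-12:
        return []
    ts = np.linspace(lo, hi, n_scan)
    vals = np.array([g(t) for t in ts])
    roots = []
    for i in np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]:
        roots.append(brentq(g, ts[i], ts[i + 1], xtol=1e-12))
    # grid points that are exact zeros
    for i in np.nonzero(vals == 0.0)[0]:
        roots.append(float(ts[i]))
    return roots


def _interior_A(T: float, params: ClimateParams) -> float:
    """Vegetation fraction on the nontrivial nullcline, A = 1 - gamma/beta(T)."""
    beta = float(growth_rate(T, params))
    return 1.0 - params.gamma / beta


def find_equilibria(params: ClimateParams,
                    T_box: tuple[float, float] = T_BOX) -> list[Equilibrium]:
    """Find and classify all equilibria inside the temperature box.

    Two one-dimensional searches: (a) the vegetation-free branch A = 0, where
    the energy balance (1 - alpha(T, 0)) Q0 = R0(T) is solved piecewise on the
    three ocean-albedo segments; (b) the interior branch A(T) = 1 -
    gamma/beta(T), defined wherever beta(T) > gamma, substituted into the
    energy balance.  Roots within 1e-6 K of each other are merged.  Each
    equilibrium carries its Jacobian eigenvalues and stability class.
    """
    lo, hi = T_box
    q = params.Q0

    def bare_residual(T: float) -> float:
        alpha = ((1.0 - params.p) * float(ocean_albedo(T, params))
                 + params.p * params.alpha_g)
        return (1.0 - alpha) * q - float(outgoing_radiation(T, params))

    def interior_residual(T: float) -> float:
        A = _interior_A(T, params)
        alpha = ((1.0 - params.p) * float(ocean_albedo(T, params))
                 + params.p * (params.alpha_g + (params.alpha_v - params.alpha_g) * A))
        return (1.0 - alpha) * q - float(outgoing_radiation(T, params))

    seams = [params.T_alpha_l, params.T_alpha_u]
    found: list[tuple[float, float, str]] = []  # (T, A, branch)

    # (a) vegetation-free branch
    edges = sorted({lo, hi, *[s for s in seams if lo < s < hi]})
    for a, b in zip(edges[:-1], edges[1:]):
        for T in _segment_roots(bare_residual, a, b, n_scan=4001):
            found.append((T, 0.0, "vegetation-free"))

    # (b) interior branch: beta(T) > gamma requires gamma < 1
    if params.gamma < 1.0:
        s = math.sqrt((1.0 - params.gamma) / params.k)
        ilo = max(lo, params.T_opt - s)
        ihi = min(hi, params.T_opt + s)
        if ihi > ilo:
            # inset slightly from the support edge, where A(T) -> 0 steeply
            eps_edge = 1e-9
            edges = sorted({ilo + eps_edge, ihi - eps_edge,
                            *[t for t in seams if ilo < t < ihi]})
            for a, b in zip(edges[:-1], edges[1:]):
                for T in _segment_roots(interior_residual, a, b, n_scan=20001):
                    found.append((T, _interior_A(T, params), "interior"))

    # merge duplicates and classify
    found.sort()
    merged: list[tuple[float, float, str]] = []
    for T, A, branch in found:
        if merged and abs(T - merged[-1][0]) < 1e-6 and abs(A - merged[-1][1]) < 1e-6:
            continue
        merged.append((T, A, branch))

    eqs = []
    for T, A, branch in merged:
        eigs = np.linalg.eigvals(jacobian((T, A), params))
        eqs.append(Equilibrium(State(T, A), branch,
                               (complex(eigs[0]), complex(eigs[1])),
                               _classify(eigs)))
    return eqs


def warm_equilibrium(params: ClimateParams) -> Equilibrium:
    """The interior equilibrium with the highest temperature (warm focus)."""
    interior = [e for e in find_equilibria(params) if e.branch == "interior"]
    if not interior:
        raise ValueError(f"no interior equilibrium for gamma={params.gamma}")
    return max(interior, key=lambda e: e.state.T)


def saddle_equilibrium(params: ClimateParams) -> Equilibrium:
    saddles = [e for e in find_equilibria(params) if e.stability == "saddle"]
    if not saddles:
        labels = [(e.state.T, e.stability) for e in find_equilibria(params)]
        raise ValueError(f"no saddle equilibrium found; equilibria: {labels}")
    return saddles[0]


# ----------------------------------------------------------------------
# limit cycle and Hopf transition

def detect_limit_cycle(params: ClimateParams, t_settle: float = 1000.0,
                       t_obs: float = 4000.0, dt: float = 0.01,
                       amp_tol: float = 1e-6,
                       max_t: float = 3e5) -> CycleSummary | None:
    """Detect the warm limit cycle by forward integration.

    Starts from the warm interior equilibrium perturbed by 1e-3 K and
    integrates in windows of ``t_obs`` years until successive T-maxima
    stabilize; the period is the mean spacing of those maxima.  The initial
    transient ``t_settle`` is extended using the linearization: for a stable
    focus, long enough for the perturbation to decay below ``amp_tol``
    (then ``None`` is returned); for an unstable focus, long enough for the
    weak exponential growth (Re(lambda) can be ~1e-4 yr^-1 here) to reach
    finite amplitude.  Raises :class:`ColdBasinEscape` if the trajectory
    leaves the warm basin, and ``RuntimeError`` if the oscillation neither
    converges nor decays within ``max_t`` years.
    """
    eq = warm_equilibrium(params)
    re = eq.max_real_part
    perturb = 1e-3
    if re < 0:
        t_settle = max(t_settle, 1.5 * math.log(perturb / amp_tol) / (-re))
    elif re > 0:
        t_settle = max(t_settle, min(math.log(0.3 / perturb) / re, max_t / 2))
    t_settle = min(t_settle, max_t)

    state = State(eq.state.T + perturb, eq.state.A)
    traj = integrate_ode(state, params, t_max=t_settle, dt=dt, record_stride=1000)
    state = traj.final_state
    t_done = t_settle
    prev_amp = None
    while t_done < max_t + t_obs:
        traj = integrate_ode(state, params, t_max=t_obs, dt=dt, record_stride=10)
        state = traj.final_state
        if state.T < 260.0:
            raise ColdBasinEscape(
                f"trajectory from the warm equilibrium escaped to the cold "
                f"basin (T={state.T:.2f} K at t={t_done + t_obs:g} yr)")
        amp = float(traj.T.max() - traj.T.min())
        if amp < amp_tol:
            return None
        peaks, _ = find_peaks(traj.T, prominence=0.1 * amp)
        heights = traj.T[peaks]
        settled = (len(peaks) >= 3
                   and np.max(np.abs(np.diff(heights))) < 1e-5 * max(1.0, amp)
                   and prev_amp is not None
                   and abs(amp - prev_amp) < 1e-3 * amp)
        if settled:
            period = float(np.mean(np.diff(traj.times[peaks])))
            return CycleSummary(period=period,
                                T_range=(float(traj.T.min()), float(traj.T.max())),
                                A_range=(float(traj.A.min()), float(traj.A.max())))
        prev_amp = amp
        t_done += t_obs
    raise RuntimeError(
        f"oscillation neither converged nor decayed within {max_t:g} yr "
        f"(last window amplitude {amp:.3g} K)")


def scan_hopf(params: ClimateParams, gamma_grid) -> dict:
    """Stability of the warm interior equilibrium along a gamma grid.

    Returns a table of per-gamma records (equilibrium location, eigenvalues,
    stability) and the Hopf bracket: the adjacent grid pair across which the
    largest eigenvalue real part changes sign from + to -.
    """
    gamma_grid = list(gamma_grid)
    if gamma_grid != sorted(gamma_grid):
        raise ValueError("gamma grid must be sorted ascending")
    rows = []
    for g in gamma_grid:
        try:
            eq = warm_equilibrium(params.with_gamma(g))
        except ValueError:
            rows.append({"gamma": g, "exists": False})
            continue
        rec = eq.to_dict()
        rec.update(gamma=g, exists=True, re_max=eq.max_real_part)
        rows.append(rec)
    bracket = None
    ok = [r for r in rows if r["exists"]]
    for r0, r1 in zip(ok[:-1], ok[1:]):
        if r0["re_max"] > 0 and r1["re_max"] < 0:
            bracket = (r0["gamma"], r1["gamma"])
            break
    return {"table": rows, "hopf_bracket": bracket}


def refine_hopf(params: ClimateParams, lo: float, hi: float,
                tol: float = 1e-3) -> tuple[float, float]:
    """Bisect the Hopf bracket (sign change of Re lambda) to width ``tol``."""

    def re_max(g: float) -> float:
        return warm_equilibrium(params.with_gamma(g)).max_real_part

    flo, fhi = re_max(lo), re_max(hi)
    if not (flo > 0 > fhi):
        raise ValueError(f"({lo}, {hi}) does not bracket a +/- sign change")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if re_max(mid) > 0:
            lo = mid
        else:
            hi = mid
    return lo, hi


# ----------------------------------------------------------------------
# separatrix and basins

def compute_separatrix(params: ClimateParams, max_arclength: float = 2000.0,
                       dt: float = 0.01,
                       box: tuple[float, float] = T_BOX) -> np.ndarray:
    """Trace the separatrix (stable manifold of the saddle).

    Integrates in reverse time from the saddle displaced by 1e-6 along each
    side of the stable eigenvector until the trajectory leaves the box
    T in [box], A in [0, 1], or the accumulated arclength (K units; A scaled
    by the box height so both axes are commensurate) exceeds
    ``max_arclength``.  Returns a polyline as an (n, 2) array of (T, A) rows
    with the saddle in the middle.

    Raises ``ValueError`` if the system has no saddle.
    """
    sad = saddle_equilibrium(params)
    J = jacobian(sad.state, params)
    eigvals, eigvecs = np.linalg.eig(J)
    stable_idx = int(np.argmin(eigvals.real))
    if eigvals[stable_idx].real >= 0 or abs(eigvals[stable_idx].imag) > 1e-12:
        raise ValueError("saddle does not have a real negative eigenvalue")
    v = np.real(eigvecs[:, stable_idx])
    v = v / np.linalg.norm(v)

    f = _scalar_drift(params)
    a_scale = box[1] - box[0]  # K per unit A for arclength accounting

    def trace(sign: float) -> list[tuple[float, float]]:
        T = sad.state.T + sign * 1e-6 * v[0]
        A = sad.state.A + sign * 1e-6 * v[1]
        pts = []
        s = 0.0
        h2, h6 = dt / 2.0, dt / 6.0
        while box[0] <= T <= box[1] and 0.0 <= A <= 1.0 and s < max_arclength:
            pts.append((T, A))
            # reverse-time RK4
            k1t, k1a = f(T, A)
            k2t, k2a = f(T - h2 * k1t, A - h2 * k1a)
            k3t, k3a = f(T - h2 * k2t, A - h2 * k2a)
            k4t, k4a = f(T - dt * k3t, A - dt * k3a)
            dT = -h6 * (k1t + 2.0 * (k2t + k3t) + k4t)
            dA = -h6 * (k1a + 2.0 * (k2a + k3a) + k4a)
            T += dT
            A += dA
            s += math.hypot(dT, a_scale * dA)
        return pts

    left = trace(-1.0)
    right = trace(+1.0)
    poly = left[::-1] + [(sad.state.T, sad.state.A)] + right
    return np.array(poly)


@lru_cache(maxsize=32)
def warm_region(params: ClimateParams) -> tuple[float, float, float, float]:
    """Bounding box (T_lo, T_hi, A_lo, A_hi) of the warm attractor set,
    padded by 2 K in T and 0.1 in A (the attractor may be a cycle)."""
    cycle = detect_limit_cycle(params)
    if cycle is None:
        eq = warm_equilibrium(params)
        tlo = thi = eq.state.T
        alo = ahi = eq.state.A
    else:
        tlo, thi = cycle.T_range
        alo, ahi = cycle.A_range
    return (tlo - 2.0, thi + 2.0, max(0.0, alo - 0.1), min(1.0, ahi + 0.1))


def _snowball_T(params: ClimateParams) -> float:
    eqs = [e for e in find_equilibria(params) if e.branch == "vegetation-free"
           and e.is_stable]
    return eqs[0].state.T


def basin_of(state0: State, params: ClimateParams, t_max: float = 2000.0,
             dt: float = 0.01) -> str:
    """Label the basin of an initial condition: 'warm', 'cold' or 'undecided'.

    Integrates forward and classifies the endpoint: cold if within 1 K of the
    snowball temperature, warm if inside the padded bounding box of the warm
    attractor set, undecided otherwise.
    """
    traj = integrate_ode(state0, params, t_max=t_max, dt=dt, record_stride=100)
    T, A = traj.final_state
    if abs(T - _snowball_T(params)) < 1.0:
        return "cold"
    tlo, thi, alo, ahi = warm_region(params)
    if tlo <= T <= thi and alo <= A <= ahi:
        return "warm"
    return "undecided"


def basin_labels(T0, A0, params: ClimateParams, t_max: float = 2000.0,
                 dt: float = 0.01) -> np.ndarray:
    """Vectorized :func:`basin_of` over arrays of initial conditions.

    Integrates all initial states simultaneously with RK4 and labels the
    endpoints; returns an object array of 'warm' / 'cold' / 'undecided'.
    """
    T = np.array(T0, dtype=float).ravel().copy()
    A = np.array(A0, dtype=float).ravel().copy()
    n = int(round(t_max / dt))
    h2, h6 = dt / 2.0, dt / 6.0

    def f(Tv, Av):
        return drift((Tv, Av), params)

    for _ in range(n):
        k1t, k1a = f(T, A)
        k2t, k2a = f(T + h2 * k1t, A + h2 * k1a)
        k3t, k3a = f(T + h2 * k2t, A + h2 * k2a)
        k4t, k4a = f(T + dt * k3t, A + dt * k3a)
        T += h6 * (k1t + 2.0 * (k2t + k3t) + k4t)
        A += h6 * (k1a + 2.0 * (k2a + k3a) + k4a)
        np.clip(A, 0.0, 1.0, out=A)

    labels = np.full(T.shape, "undecided", dtype=object)
    labels[np.abs(T - _snowball_T(params)) < 1.0] = "cold"
    tlo, thi, alo, ahi = warm_region(params)
    warm = (T >= tlo) & (T <= thi) & (A >= alo) & (A <= ahi)
    labels[warm & (labels == "undecided")] = "warm"
    return labels.reshape(np.shape(T0))
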