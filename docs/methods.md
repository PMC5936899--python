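# Methods

## Model

`climveg` implements a zero-dimensional conceptual model of the coupled
evolution of global mean temperature `T` (kelvin) and vegetated land
fraction `A` (dimensionless), of the Rombouts–Ghil type:

    C_T dT/dt = (1 − α(T, A)) Q0 − R0(T)
       dA/dt = β(T) A (1 − A) − γ A

with

    α(T, A)  = (1 − p) α_o(T) + p (α_v A + α_g (1 − A))
    α_o(T)   = ramp from α_max (T ≤ T_α,ℓ, ice-covered ocean)
               down to α_min (T > T_α,u, ice-free), linear in between
    R0(T)    = B0 + B1 (T − T_opt)
    β(T)     = max(0, 1 − k (T − T_opt)²)

Two feedbacks shape the phase portrait. The ice–albedo feedback (through
`α_o`) makes the energy balance bistable: a "snowball" state with
ice-covered ocean and no vegetation coexists with a warm state near 300 K.
The vegetation–albedo feedback (vegetation is darker than bare ground,
`α_v < α_g`) couples the two equations: vegetation loss raises albedo and
cools, while cooling toward `T_opt` initially *accelerates* vegetation
growth, giving the characteristic relaxation oscillations of the warm
state.

The stochastic extension perturbs the growth rate with Gaussian white
noise, `β(T) → β(T) + ε ξ(t)`, so the vegetation equation becomes the Itô
SDE

    dA = [β(T) A(1−A) − γ A] dt + ε A(1−A) dW.

The multiplicative factor `A(1−A)` vanishes at both edges, so `A = 0`
(bare planet) and `A = 1` are invariant for the exact process. ε carries
the units of the growth rate (yr⁻¹) with the √yr of the Wiener increment
absorbed into `dW`; no physical calibration of ε is asserted.

## Default parameters

| symbol | default | units | meaning |
|---|---|---|---|
| C_T | 500 | W yr K⁻¹ m⁻² | effective heat capacity |
| Q0 | 342.5 | W m⁻² | incoming solar flux |
| p | 0.3 | – | land fraction of the planet |
| α_v, α_g | 0.1, 0.4 | – | vegetation / bare-ground albedo |
| α_max, α_min | 0.85, 0.25 | – | ice-covered / ice-free ocean albedo |
| T_α,ℓ, T_α,u | 263, 300 | K | ocean-albedo ramp edges |
| B0, B1 | 200, 2.5 | W m⁻², W K⁻¹ m⁻² | outgoing-flux constant and slope |
| T_opt | 283 | K | optimal vegetation growth temperature |
| k | 0.004 | yr⁻¹ K⁻² | growth-curve width |
| γ | (scan) | yr⁻¹ | vegetation death rate |

All temperatures are absolute kelvin; the time unit is years throughout.
Parameters are validated once at construction (`α_v < α_g`,
`α_min < α_max`, ramp edges ordered, albedos and `p` in [0, 1], positive
rates); the evaluation functions then assume validity.

With these values the model has exactly three equilibria for every death
rate in (0, 1): the snowball state at `T = T_opt + ((1−α)Q0 − B0)/B1 =
242.045 K` (closed form; γ-independent), an interior saddle whose stable
manifold is the separatrix between the cold and warm basins, and a warm
interior state near 294–299 K. The warm state is an unstable focus
surrounded by a stable limit cycle for small γ and becomes stable through
a supercritical Andronov–Hopf bifurcation; on the panel grid
{0.001, 0.01, 0.02, 0.025, 0.1, 0.35} the sign change of Re λ lies in
(0.025, 0.1) (bisection places it near 0.027).

## Numerics

**Equilibrium enumeration.** Both nullcline branches reduce to 1-D root
problems in `T`: the vegetation-free branch `A = 0`, and the interior
branch obtained by eliminating `A` through `A(T) = 1 − γ/β(T)` wherever
`β(T) > γ`. The branch residual (absorbed minus outgoing flux) is only
piecewise smooth — kinks at the two ramp temperatures and at the edges of
the β support — so each continuity segment is scanned on a dense grid
(4 001 points on the bare branch, 20 001 on the interior branch, where
`A(T)` steepens sharply near the support edge) and sign changes are
refined with Brent's method to `xtol = 1e-12`. Roots within 1e-6 K are
merged. Each equilibrium is classified from the eigenvalues of the
analytic Jacobian; at a non-differentiable seam the derivative is taken
one-sidedly after a 1e-9 K nudge (no default equilibrium sits on a seam).

**Deterministic integration.** Fixed-step classical RK4 at `dt = 0.01 yr`,
sharing the stochastic scheme's grid so deterministic and stochastic runs
are directly comparable. `A` is clamped to [0, 1] after each step; the
clamp is inactive except for machine-precision excursions at the invariant
edges. Halving `dt` moves 1000-yr endpoints by < 1e-6 K.

**Limit-cycle detection.** Near the Hopf point the focus is only weakly
unstable (Re λ ~ 1e-4–1e-3 yr⁻¹), so a fixed transient from a small
perturbation would measure an unconverged spiral. The detector therefore
sizes the transient from the linearization (long enough for a 1e-3
perturbation to grow to finite amplitude, or to decay below 1e-6 for a
stable focus) and then integrates in 4 000-yr windows until successive
T-maxima agree to 1e-5 of the amplitude; the period is the mean spacing of
those maxima. For γ = 0.01 / 0.02 the converged cycle spans roughly
297.9–301.0 K / 297.5–300.2 K with periods near 1 090 / 830 yr — the
period shrinks as γ grows, and the cycle grazes `A ≈ 0` during its long
slow-cooling phase.

**Separatrix.** Reverse-time RK4 from the saddle displaced by ±1e-6 along
the stable eigenvector, stopped at the box T ∈ [230, 310], A ∈ [0, 1] or
at a 2 000 K accumulated arclength (A scaled by the box height). In
reverse time the transverse (forward-unstable) direction is contracting,
so the trace is numerically stable. Away from the saddle the polyline
hugs `A ≈ 0` at astronomically small values — the warm basin extends to
extremely small vegetation fractions at high temperature.

**Stochastic scheme.** Euler–Maruyama at `dt = 0.01 yr` (Itô, as the
scheme implies): a plain Euler step for `T` (which carries no noise) and
one `N(0,1)` deviate per step for `A`. Clamping to [0, 1] (rather than
rejection or reflection) preserves the invariant edges that the exact SDE
respects; the clamp activates on < 1 % of steps at ε ≤ 0.2. Each ensemble
member `i` owns the stream of `PCG64(base_seed + i)`, consumed in fixed
4 096-step chunks, so a batch member is bit-identical to a solo run with
the same seed and the whole pipeline is reproducible byte-for-byte from
the seed.

## Transition statistics

A *transition* is the first passage of `T` below 260 K — below every
saddle temperature (279–287 K for the γ values studied) and well above the
snowball (242 K), so crossings are unambiguous and effectively
irreversible. The *window* of a probability curve over ε is
(smallest grid ε with escape fraction ≥ 0.1, smallest with ≥ 0.9), an
operationalization of "transitions begin / become certain"; both the raw
curve with Wilson 95 % intervals and the window are reported. Defaults:
100 runs per grid point, grid step 0.05, horizon 5 000 yr, warm-attractor
start (the stable warm equilibrium, or a point settled onto the limit
cycle by a 5 000-yr deterministic integration when the equilibrium is
unstable).

Stationary temperature densities are pooled normalized histograms after a
500-yr burn-in. At large ε many runs crash within the horizon; to
quantify the *pre-crash* noise-induced shift without the snowball mass
dominating, a `pre_transition` variant keeps only samples before each
run's first passage. Both variants are available and the shift table
(mean, mode, central 90 % interval per ε) flags whether the mean
temperature decreases monotonically with ε.

### Mechanism and the location of the windows

For `X = log A` Itô's formula gives

    dX = [β(T)(1−A) − γ − ε²(1−A)²/2] dt + ε(1−A) dW,

so noise on the growth rate *systematically* lowers the effective
vegetation growth by ε²/2 near `A ≈ 0`. A crash is a two-stage event:
noise must first hold vegetation collapsed while the bare planet cools,
and the collapse must then survive the passage through the high-growth
band around `T_opt = 283 K` where `β ≈ 1` far exceeds any death rate
studied. That second stage sets the scale of the windows: under the
default conditions the simulated escape windows sit at ε of order
0.65–1.0 (measured by the sweeps: roughly (0.70, 0.85) at γ = 0.01,
(0.95, 1.00) at γ = 0.1, (0.65, 0.70) at γ = 0.35), with the edges
shifting upward from γ = 0.01 to γ = 0.1, probability monotone in ε, and
the γ = 0.35 system crashing readily at ε = 0.7 after a visible
noise-induced shift of the pre-crash temperature distribution toward
lower means and larger spread.

## Problem sizes

The shipped tests and the acceptance script use desk-scale sizes chosen to
resolve each quantity without excess: 100 runs per sweep point (binomial
standard error ≤ 0.05), 10–20 runs for density estimates (≥ 4×10⁵ pooled
samples), 2 000-yr deterministic averages with a 1 000-yr transient
discarded, and 5 000-yr stochastic horizons matching the study conditions.

## Known limitations

- Zero-dimensional: no spatial structure, seasonal forcing, CO₂ dynamics
  or ocean heat transport; `ε` is a free parameter, not calibrated to any
  observed variability.
- Densities are empirical histograms; no Fokker–Planck solver or
  quasipotential/large-deviation machinery is included, so window edges
  carry the binomial uncertainty of the ensemble size and the 0.05 grid
  resolution.
- The Hopf bifurcation's supercritical character is observed (stable cycle
  for γ below the bracket), not proven via normal-form coefficients.
- The synthetic study conditions are exactly the model's own dynamics;
  passing tests show the solver and statistics are correct for this model,
  not that the model describes any particular real climate record.
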