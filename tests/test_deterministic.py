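"""Equilibria, stability, limit cycle, Hopf transition, separatrix, basins."""

import numpy as np
import pytest

from climveg import (ClimateParams, State, basin_of, compute_separatrix,
                     detect_limit_cycle, drift, find_equilibria,
                     integrate_ode, refine_hopf, scan_hopf, warm_equilibrium)
from climveg.deterministic import basin_labels

GAMMA_GRID = [0.001, 0.01, 0.02, 0.025, 0.1, 0.35]


class TestEquilibria:
    def test_three_equilibria_structure_g002(self, equilibria_cache):
        eqs = equilibria_cache(0.02)
        assert len(eqs) == 3
        by_T = sorted(eqs, key=lambda e: e.state.T)
        cold, saddle, warm = by_T
        assert cold.branch == "vegetation-free" and cold.is_stable
        assert cold.state.T == pytest.approx(242.045, abs=1e-3)
        assert saddle.stability == "saddle"
        assert saddle.state.T == pytest.approx(279.0, abs=0.5)
        assert saddle.state.A == pytest.approx(0.979, abs=0.005)
        assert warm.stability == "unstable-focus"
        assert warm.state.T == pytest.approx(298.6, abs=0.2)
        assert warm.state.A == pytest.approx(0.10, abs=0.02)

    def test_three_equilibria_structure_g035(self, equilibria_cache):
        eqs = equilibria_cache(0.35)
        by_T = sorted(eqs, key=lambda e: e.state.T)
        assert [e.stability == "saddle" for e in by_T] == [False, True, False]
        assert by_T[1].state.T == pytest.approx(286.8, abs=0.5)
        assert by_T[1].state.A == pytest.approx(0.63, abs=0.01)
        assert by_T[2].is_stable
        assert by_T[2].state.T == pytest.approx(294.2, abs=0.2)

    @pytest.mark.parametrize("gamma", GAMMA_GRID)
    def test_snowball_temperature_gamma_independent(self, equilibria_cache, gamma):
        """The vegetation-free equilibrium solves a linear balance whose
        closed form T = T_opt + ((1 - alpha)Q0 - B0)/B1 does not involve
        gamma."""
        p = ClimateParams(gamma=gamma)
        alpha = (1 - p.p) * p.alpha_max + p.p * p.alpha_g
        closed = p.T_opt + ((1 - alpha) * p.Q0 - p.B0) / p.B1
        cold = [e for e in equilibria_cache(gamma) if e.branch == "vegetation-free"]
        assert len(cold) == 1
        assert cold[0].state.T == pytest.approx(closed, abs=1e-9)
        assert closed == pytest.approx(242.045, abs=1e-9)

    @pytest.mark.parametrize("gamma", GAMMA_GRID)
    def test_count_and_residuals(self, equilibria_cache, gamma):
        eqs = equilibria_cache(gamma)
        assert len(eqs) == 3
        p = ClimateParams(gamma=gamma)
        for e in eqs:
            dT, dA = drift(e.state, p)
            assert abs(dT) < 1e-9 and abs(dA) < 1e-9

    def test_saddle_eigenstructure(self, equilibria_cache):
        sad = [e for e in equilibria_cache(0.02) if e.stability == "saddle"][0]
        re = sorted(ev.real for ev in sad.eigenvalues)
        assert re[0] < 0 < re[1]
        assert all(abs(ev.imag) < 1e-12 for ev in sad.eigenvalues)


class TestIntegration:
    def test_fixed_point_stays_fixed(self):
        p = ClimateParams(gamma=0.02)
        traj = integrate_ode(State(242.045, 0.0), p, t_max=500.0,
                             record_stride=100)
        assert np.all(np.abs(traj.T - 242.045) < 1e-8)
        assert np.all(traj.A == 0.0)

    def test_cold_basin_endpoint(self):
        p = ClimateParams(gamma=0.02)
        traj = integrate_ode(State(260.0, 0.5), p, t_max=2000.0,
                             record_stride=100)
        assert traj.final_state.T == pytest.approx(242.045, abs=0.01)
        assert traj.final_state.A < 1e-6

    def test_warm_basin_mean_temperature(self):
        """Long run on the warm attractor stays near 300 K on average."""
        p = ClimateParams(gamma=0.02)
        traj = integrate_ode(State(295.0, 0.8), p, t_max=2000.0, record_stride=10)
        post = traj.after(1000.0)
        assert abs(post.T.mean() - 300.0) < 5.0

    def test_step_halving_convergence(self):
        """RK4: halving dt moves a 1000-yr endpoint by < 1e-6 K."""
        p = ClimateParams(gamma=0.02)
        s0 = State(295.0, 0.8)
        end1 = integrate_ode(s0, p, 1000.0, dt=0.01, record_stride=100000).final_state
        end2 = integrate_ode(s0, p, 1000.0, dt=0.005, record_stride=200000).final_state
        assert abs(end1.T - end2.T) < 1e-6
        assert abs(end1.A - end2.A) < 1e-7

    def test_divergence_aborts_with_diagnostic(self):
        p = ClimateParams(gamma=0.02)
        with pytest.raises(FloatingPointError, match="step"):
            integrate_ode(State(295.0, 0.8), p, t_max=3e5, dt=1e5)


class TestHopf:
    def test_stability_ordering_along_gamma(self, params):
        res = scan_hopf(params, GAMMA_GRID)
        re = {r["gamma"]: r["re_max"] for r in res["table"]}
        for g in (0.001, 0.01, 0.02, 0.025):
            assert re[g] > 0, f"warm state should be unstable at gamma={g}"
        for g in (0.1, 0.35):
            assert re[g] < 0, f"warm state should be stable at gamma={g}"
        assert res["hopf_bracket"] == (0.025, 0.1)

    def test_bisection_refines_single_crossing(self, params):
        lo, hi = refine_hopf(params, 0.025, 0.1, tol=1e-3)
        assert hi - lo <= 1e-3
        assert 0.025 < lo < hi < 0.1
        assert warm_equilibrium(params.with_gamma(lo)).max_real_part > 0
        assert warm_equilibrium(params.with_gamma(hi)).max_real_part < 0


@pytest.fixture(scope="module")
def cycles(params_for):
    return {g: detect_limit_cycle(params_for(g)) for g in (0.01, 0.02, 0.1)}


@pytest.fixture(scope="module")
def sep(params_for):
    return compute_separatrix(params_for(0.02))


class TestLimitCycle:
    def test_cycle_exists_below_hopf(self, cycles):
        c = cycles[0.02]
        assert c is not None
        assert c.T_range[1] - c.T_range[0] > 1.0
        assert c.A_range[1] > 0.5  # vegetation boom phase

    def test_no_cycle_above_hopf(self, cycles):
        assert cycles[0.1] is None

    def test_period_decreases_with_death_rate(self, cycles):
        assert cycles[0.01].period > cycles[0.02].period

    def test_cycle_encircles_warm_equilibrium(self, cycles, params_for):
        eq = warm_equilibrium(params_for(0.02)).state
        c = cycles[0.02]
        assert c.T_range[0] < eq.T < c.T_range[1]
        assert c.A_range[0] < eq.A < c.A_range[1]


class TestSeparatrixAndBasins:
    def test_saddle_on_polyline(self, sep, equilibria_cache):
        sad = [e for e in equilibria_cache(0.02) if e.stability == "saddle"][0]
        d = np.min(np.hypot(sep[:, 0] - sad.state.T, sep[:, 1] - sad.state.A))
        assert d < 1e-5

    def test_passes_near_279K(self, sep):
        assert np.any(np.abs(sep[:, 0] - 279.0) < 0.5)

    def test_sides_of_saddle_reach_different_attractors(self, equilibria_cache,
                                                        params_for):
        """Displacing the saddle along its unstable eigenvector by +/-1e-3
        commits the trajectory to the two different attractors."""
        from climveg import jacobian
        p = params_for(0.02)
        sad = [e for e in equilibria_cache(0.02) if e.stability == "saddle"][0]
        J = jacobian(sad.state, p)
        w, v = np.linalg.eig(J)
        u = np.real(v[:, int(np.argmax(w.real))])
        labels = set()
        for sign in (+1, -1):
            s0 = State(sad.state.T + sign * 1e-3 * u[0],
                       min(1.0, max(0.0, sad.state.A + sign * 1e-3 * u[1])))
            labels.add(basin_of(s0, p, t_max=8000.0))
        assert labels == {"warm", "cold"}

    def test_trivial_basin_labels(self, params_for):
        p = params_for(0.02)
        assert basin_of(State(242.05, 0.0), p) == "cold"
        assert basin_of(State(295.0, 0.8), p) == "warm"

    def test_grid_labels_split_by_separatrix(self, sep, params_for):
        """On a coarse grid every decided label agrees with the side of the
        separatrix polyline the point falls on (measured by the sign of the
        T difference at matched A where the polyline is single-valued)."""
        p = params_for(0.02)
        T0, A0 = np.meshgrid(np.linspace(255.0, 300.0, 8),
                             np.linspace(0.05, 0.95, 8))
        labels = basin_labels(T0, A0, p, t_max=3000.0)
        assert set(np.unique(labels)) <= {"warm", "cold"}
        # saddle branch of the separatrix: for each A, the boundary T
        m = (sep[:, 1] > 0.02) & (sep[:, 1] < 0.999)
        bT, bA = sep[m, 0], sep[m, 1]
        for Tq, Aq, lab in zip(T0.ravel(), A0.ravel(), labels.ravel()):
            i = int(np.argmin(np.abs(bA - Aq)))
            if abs(bA[i] - Aq) > 0.01 or abs(Tq - bT[i]) < 2.0:
                continue  # off the resolved branch or too close to call
            expected = "cold" if Tq < bT[i] else "warm"
            assert lab == expected, (Tq, Aq, lab, bT[i])
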