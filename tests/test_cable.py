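import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axonfield.cable import (CableState, FiberGeometry, MembraneParams,
                             SolverConfig, axial_current, couple_segments,
                             crank_nicolson_step, current_density,
                             initial_state, ionic_current,
                             longitudinal_current, segment_area,
                             segment_resistance, simulate, thomas_solve)
from axonfield.gating import GatingState, rate_constants


class TestGeometry:
    @pytest.mark.parametrize("r,x,expected", [
        (1.0, 1.0, 4.0 * math.pi),
        (5.0, 1.08, 60.8 * math.pi),    # node-length segment
        (2.0, 0.0, 8.0 * math.pi),      # end-cap only
    ])
    def test_segment_area(self, r, x, expected):
        g = FiberGeometry(radius=r, segment_length=x)
        assert segment_area(g) == pytest.approx(expected, rel=1e-12)

    def test_segment_resistance_unit_case_and_linearity(self):
        g = FiberGeometry(radius=1.0, segment_length=1.0, rho=1.0)
        assert segment_resistance(g) == pytest.approx(1.0 / (4.0 * math.pi))
        g2 = dataclasses.replace(g, rho=2.0)
        assert segment_resistance(g2) == pytest.approx(2 * segment_resistance(g))

    def test_zero_length_resistance_rejected(self):
        g = FiberGeometry(radius=1.0, segment_length=0.0)
        with pytest.raises(ValueError):
            segment_resistance(g)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(r=st.floats(0.1, 50.0), x=st.floats(0.01, 100.0),
           rho=st.floats(0.1, 10.0))
    def test_resistance_area_identity(self, r, x, rho):
        """R·A = ρx: the resistance form is ρL/A with the lateral+cap area."""
        g = FiberGeometry(radius=r, segment_length=x, rho=rho)
        assert segment_resistance(g) * segment_area(g) == pytest.approx(
            rho * x, rel=1e-12)

    def test_node_with_myelin_rejected(self):
        with pytest.raises(ValueError):
            FiberGeometry(radius=1.0, segment_length=1.0,
                          segment_type="node", myelin_thickness=1.0)


class TestCurrents:
    def test_ionic_current_all_closed_is_zero(self):
        p = MembraneParams(g_L=1e-300)
        assert ionic_current(0.0, GatingState(0.0, 0.0, 0.0), p) == pytest.approx(
            0.0, abs=1e-290)

    def test_ionic_current_zero_driving_force(self):
        p = MembraneParams(g_L=1e-300)
        s = GatingState(m=0.0, n=0.7, h=0.0)
        assert ionic_current(p.V_K, s, p) == pytest.approx(0.0, abs=1e-290)

    def test_ionic_current_peak_conductance_sum(self):
        """With all gates open, V=0 and the sign-flipped reversal convention
        (V_K=-12, V_Na=115), I = 12.5·12 + 28·(-115) = -3070."""
        p = MembraneParams(gbar_K=12.5, gbar_Na=28.0, g_L=1e-300,
                           V_K=-12.0, V_Na=115.0)
        s = GatingState(m=1.0, n=1.0, h=1.0)
        assert ionic_current(0.0, s, p) == pytest.approx(-3070.0, rel=1e-12)

    def test_longitudinal_current_modes(self):
        assert longitudinal_current(0.0, 2.0) == 0.0
        assert longitudinal_current(10.0, 2.0, mode="dimensional") == 5.0
        lit = longitudinal_current(None, 2.0, mode="literal_paper",
                                   V_prev=3.0, step_term=1.0)
        assert lit == pytest.approx(8.0)
        with pytest.raises(ValueError):
            longitudinal_current(1.0, 0.0)

    def test_axial_current_resistive_term_only(self):
        """With vanishing ionic fractions and closed gates only R·V survives."""
        p = MembraneParams(gamma=1e-30, delta=1e-30, g_L=1e-300)
        s = GatingState(m=0.0, n=0.0, h=0.0)
        got = axial_current(5.0, s, p, R=1.0, step=0.0)
        assert got == pytest.approx(5.0, abs=1e-20)

    def test_axial_current_matches_independent_evaluation(self, rng):
        """Plain-python re-implementation of the axial-current expression
        agrees to 1e-12 relative on random states."""
        p = MembraneParams(gamma=0.3, delta=0.2, eta=0.1)
        R, step = 0.007, 0.5
        for _ in range(10):
            V = float(rng.uniform(-80, 40))
            m, n, h = rng.uniform(0.05, 0.95, 3)
            s = GatingState(m=m, n=n, h=h)
            rs = rate_constants(V)
            I_ion = (p.gbar_K * n**4 * (V - p.V_K)
                     + p.gbar_Na * m**3 * h * (V - p.V_Na)
                     + p.g_L * (V - p.V_L))
            Vp = V + step * I_ion / p.C_m
            n1 = n + step * (rs.alpha_n * (1 - n) - rs.beta_n * n)
            m1 = m + step * (rs.alpha_m * (1 - m) - rs.beta_m * m)
            h1 = h + step * (rs.alpha_h * (1 - h) - rs.beta_h * h)
            n1, m1, h1 = (min(max(v, 0.0), 1.0) for v in (n1, m1, h1))
            expected = (p.gamma * p.gbar_K * n1**4 * (Vp - p.V_K)
                        + p.delta * p.gbar_Na * m1**3 * h1 * (Vp - p.V_Na)
                        + R * Vp)
            got = axial_current(V, s, p, R=R, step=step)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_current_density(self):
        assert current_density(0.0, 3.0) == 0.0
        assert current_density(4 * math.pi, 4 * math.pi) == 1.0
        assert current_density(6.0, 2.0) == 3 * current_density(2.0, 2.0)
        with pytest.raises(ValueError):
            current_density(1.0, 0.0)

    def test_couple_segments_rule_and_constraint(self):
        assert couple_segments(2.5, 1.0) == 2.5
        assert couple_segments(2.0, 1.05) == pytest.approx(2.1)
        with pytest.raises(ValueError, match="J"):
            couple_segments(1.0, 0.9)
        assert couple_segments(1.0, 0.9, allow_dissipative=True) == pytest.approx(0.9)
        with pytest.raises(ValueError):
            couple_segments(1.0, 0.0)

    def test_coupling_is_monotone_for_amplifying_K(self):
        """K >= 1 never decreases |J| along successive applications."""
        for K in (1.0, 1.01, 1.5, 3.0):
            J = 0.37
            seq = [J]
            for _ in range(20):
                seq.append(float(couple_segments(seq[-1], K)))
            assert all(b >= a for a, b in zip(seq, seq[1:]))

    def test_membrane_params_validate_fractions_and_K(self):
        with pytest.raises(ValueError):
            MembraneParams(gamma=0.0)
        with pytest.raises(ValueError):
            MembraneParams(K_couple=0.5)
        MembraneParams(K_couple=0.5, allow_dissipative=True)  # override path


class TestThomasSolver:
    def test_matches_dense_solve(self, rng):
        n = 30
        lower = rng.uniform(-1, 1, n - 1)
        upper = rng.uniform(-1, 1, n - 1)
        diag = rng.uniform(3, 5, n)  # diagonally dominant
        rhs = rng.uniform(-1, 1, n)
        A = np.diag(diag) + np.diag(lower, -1) + np.diag(upper, 1)
        assert thomas_solve(lower, diag, upper, rhs) == pytest.approx(
            np.linalg.solve(A, rhs), rel=1e-12)

    def test_singular_system_reports_diagonal(self):
        with pytest.raises(np.linalg.LinAlgError, match="diagonal 0"):
            thomas_solve(np.array([1.0]), np.array([0.0, 1.0]),
                         np.array([1.0]), np.array([1.0, 1.0]))


def _zero_state(n):
    z = np.zeros(n)
    return CableState(V=z.copy(), gating=GatingState(m=z.copy(), n=z.copy(),
                                                     h=z.copy()),
                      I_ion=z.copy(), I_cap=z.copy(), I_lng=z.copy(),
                      I_ax=z.copy(), J=z.copy())


class TestCrankNicolson:
    def test_zero_state_is_fixed_point(self, node_geometry):
        p = MembraneParams(g_L=1e-300)
        cfg = SolverConfig(n_segments=5, coupling="k-rule")
        new = crank_nicolson_step(_zero_state(5), p, node_geometry, cfg)
        assert new.V == pytest.approx(np.zeros(5), abs=1e-14)

    def test_symmetric_profile_stays_symmetric(self, node_geometry, membrane):
        cfg = SolverConfig(n_segments=9, coupling="k-rule")
        state = _zero_state(9)
        V = np.exp(-0.5 * (np.arange(9) - 4.0) ** 2)
        state = dataclasses.replace(state, V=V)
        for _ in range(5):
            state = crank_nicolson_step(state, membrane, node_geometry, cfg)
        assert state.V == pytest.approx(state.V[::-1], abs=1e-12)

    def test_three_segment_step_matches_dense_oracle(self, node_geometry):
        """The tridiagonal CN solve equals a dense linear-algebra solve of
        the same discrete system, built independently here."""
        p = MembraneParams(G_m=0.7, g_L=1e-300)
        cfg = SolverConfig(dt=0.01, dx=2.0, n_segments=3, coupling="k-rule")
        state = dataclasses.replace(_zero_state(3), V=np.array([1.0, -2.0, 0.5]))
        new = crank_nicolson_step(state, p, node_geometry, cfg)

        R = segment_resistance(node_geometry)
        a = node_geometry.diameter / (4 * R) / cfg.dx ** 2
        L = np.array([[-1.0, 1.0, 0.0], [1.0, -2.0, 1.0], [0.0, 1.0, -1.0]])
        Cdt = p.C_m / cfg.dt
        A = (Cdt + p.G_m / 2) * np.eye(3) - (a / 2) * L
        b = (Cdt - p.G_m / 2) * state.V + (a / 2) * (L @ state.V)
        assert new.V == pytest.approx(np.linalg.solve(A, b), rel=1e-12)

    def test_sealed_boundaries_conserve_mean_voltage(self, node_geometry):
        """With J = 0 and G_m = 0 the CN diffusion operator conserves the
        spatial mean across a step."""
        p = MembraneParams(G_m=0.0, g_L=1e-300)
        cfg = SolverConfig(n_segments=12, coupling="k-rule", boundary="sealed")
        state = dataclasses.replace(_zero_state(12),
                                    V=np.sin(np.linspace(0, 3, 12)) + 2.0)
        mean0 = state.V.mean()
        for _ in range(10):
            state = crank_nicolson_step(state, p, node_geometry, cfg)
        assert state.V.mean() == pytest.approx(mean0, rel=1e-10)


class TestSimulate:
    def test_rest_state_is_stable(self, membrane, node_geometry, quiet_solver):
        run = simulate(membrane, node_geometry, quiet_solver)
        assert np.max(np.abs(run.V - quiet_solver.V_rest)) < 1e-6

    def test_identical_config_is_bit_identical(self, membrane, node_geometry):
        cfg = SolverConfig(n_segments=8, n_steps=40, stim_amplitude=30.0,
                           stim_duration=0.02, coupling="axial")
        r1 = simulate(membrane, node_geometry, cfg)
        r2 = simulate(membrane, node_geometry, cfg)
        assert np.array_equal(r1.V, r2.V)
        assert np.array_equal(r1.J, r2.J)

    def test_effective_K_diagnostic_reports_k_rule_constant(self, node_geometry):
        p = MembraneParams(K_couple=1.25)
        cfg = SolverConfig(n_segments=5, n_steps=10, coupling="k-rule")
        state = initial_state(cfg)
        state = dataclasses.replace(state, J=np.full(5, 0.1))
        run = simulate(p, node_geometry, cfg, state=state)
        ratios = run.effective_K[np.isfinite(run.effective_K)]
        assert len(ratios) > 0
        assert np.allclose(ratios, 1.25)

    def test_halving_dt_converges_second_order(self, membrane, node_geometry):
        """Richardson-style check: CN error shrinks ~4x when dt halves."""
        def final_V(dt):
            cfg = SolverConfig(dt=dt, n_segments=6, n_steps=int(round(0.4 / dt)),
                               stim_amplitude=40.0, stim_duration=0.1,
                               coupling="axial")
            return simulate(membrane, node_geometry, cfg).V[-1]

        V1, V2, V4 = final_V(0.02), final_V(0.01), final_V(0.005)
        e1 = np.linalg.norm(V1 - V4)
        e2 = np.linalg.norm(V2 - V4)
        assert e2 < e1  # converging
        # second-order: e1/e2 ~ (2^2 * (1 - 1/4)) / (1 - 1/16)-ish; allow slack
        assert e1 / e2 > 2.5

    def test_stimulus_depolarizes_locally(self, membrane, node_geometry):
        cfg = SolverConfig(n_segments=10, n_steps=100, dt=0.005,
                           stim_segment=0, stim_amplitude=50.0,
                           stim_duration=0.2, coupling="axial")
        run = simulate(membrane, node_geometry, cfg)
        assert run.V[-1, 0] > cfg.V_rest + 1.0
        assert run.V.max() > run.V[0].max()
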