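"""Spectral master-equation solver, equilibria and protocol simulation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from p2xkin.model import CouplingFactors, ModelVariant, generator_matrix
from p2xkin.relax import (
    ConcentrationProtocol,
    binding_occupancy_curve,
    concentration_po_curve,
    equilibrium_distribution,
    simulate_protocol,
    solve_relaxation,
)
from tests.conftest import random_rate_set


def two_state_Q(k_f=2.0, k_b=1.0) -> np.ndarray:
    return np.array([[-k_f, k_b], [k_f, -k_b]])


class TestSolveRelaxation:
    def test_two_state_analytic(self):
        Q = two_state_Q()
        traj = solve_relaxation(Q, [1.0, 0.0], np.array([0.0, 100.0]))
        np.testing.assert_allclose(traj.occupancies[0], [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(traj.occupancies[-1], [1 / 3, 2 / 3], atol=1e-10)

    def test_identity_at_t0(self, fixture_rates, rng):
        Q = generator_matrix(fixture_rates, 2.0)
        p0 = rng.dirichlet(np.ones(10))
        traj = solve_relaxation(Q, p0, np.array([0.0]))
        np.testing.assert_allclose(traj.occupancies[0], p0, atol=1e-12)

    def test_matches_stiff_integrator(self, rng):
        """Eigen solution vs LSODA oracle on random rate sets."""
        for _ in range(10):
            rates = random_rate_set(rng)
            Q = generator_matrix(rates, 1.0)
            p0 = np.zeros(10)
            p0[0] = 1.0
            ts = np.linspace(0.0, 5.0, 40)
            spectral = solve_relaxation(Q, p0, ts).occupancies
            sol = solve_ivp(lambda t, p: Q @ p, (0, 5.0), p0, t_eval=ts,
                            method="LSODA", rtol=1e-11, atol=1e-13,
                            jac=lambda t, p: Q)
            assert np.abs(spectral - sol.y.T).max() < 1e-8

    def test_probability_conserved_and_spectrum(self, rng):
        for _ in range(10):
            rates = random_rate_set(rng)
            L = float(rng.uniform(0, 100))
            Q = generator_matrix(rates, L)
            w = np.linalg.eigvals(Q)
            assert np.all(w.real <= 1e-9 * max(1.0, np.abs(Q).max()))
            p0 = np.zeros(10)
            p0[0] = 1.0
            traj = solve_relaxation(Q, p0, np.linspace(0, 10, 30))
            np.testing.assert_allclose(traj.occupancies.sum(axis=1), 1.0, atol=1e-9)

    def test_rejects_non_generator(self):
        with pytest.raises(ValueError):
            solve_relaxation(np.eye(2), [1, 0], np.array([1.0]))


class TestEquilibrium:
    def test_two_state(self):
        p = equilibrium_distribution(two_state_Q())
        np.testing.assert_allclose(p, [1 / 3, 2 / 3], atol=1e-12)

    def test_zero_concentration_all_in_c0(self, fixture_rates):
        p = equilibrium_distribution(generator_matrix(fixture_rates, 0.0))
        np.testing.assert_allclose(p, np.eye(10)[0], atol=1e-10)

    def test_null_vector_matches_long_time_limit(self, rng):
        for _ in range(5):
            rates = random_rate_set(rng, lo=0.1, hi=1000)
            Q = generator_matrix(rates, 10.0)
            p_eq = equilibrium_distribution(Q)
            assert np.abs(Q @ p_eq).max() <= 1e-10 * max(1.0, np.abs(Q).max())
            p0 = np.zeros(10)
            p0[0] = 1.0
            traj = solve_relaxation(Q, p0, np.array([1e6]))
            np.testing.assert_allclose(traj.occupancies[-1], p_eq, atol=1e-7)


class TestProtocols:
    def test_equilibrium_start_is_stationary(self, fixture_rates):
        L = 3.0
        p_eq = equilibrium_distribution(generator_matrix(fixture_rates, L))
        protocol = ConcentrationProtocol(segments=((L, 2.0),), points_per_segment=50)
        traj = simulate_protocol(fixture_rates, ModelVariant.F1, CouplingFactors(),
                                 protocol, p_init=p_eq)
        assert np.abs(traj.occupancies - p_eq).max() < 1e-9
        assert np.ptp(traj.po) < 1e-9

    def test_jump_rises_then_decays(self, fixture_rates):
        protocol = ConcentrationProtocol.jump(100.0, on=3.0, off=8.0)
        traj = simulate_protocol(fixture_rates, ModelVariant.F1, CouplingFactors(),
                                 protocol)
        po = traj.po
        n_act = traj.segment_bounds[0]
        p_eq = equilibrium_distribution(generator_matrix(fixture_rates, 100.0))
        po_sat = p_eq[7:].sum()
        assert po[0] < 1e-12
        assert po[n_act - 1] == pytest.approx(po_sat, rel=1e-3)
        assert po[-1] < 0.1 * po[n_act - 1]  # decays back toward zero
        assert np.all(np.diff(po[n_act:]) <= 1e-12)  # monotone deactivation
        assert np.all(np.diff(po[:n_act]) >= -1e-10)  # monotone activation

    def test_segment_boundary_continuity(self, fixture_rates):
        protocol = ConcentrationProtocol(
            segments=((1.0, 0.5), (10.0, 0.5), (0.0, 1.0)), points_per_segment=20)
        traj = simulate_protocol(fixture_rates, ModelVariant.F1, CouplingFactors(),
                                 protocol)
        # occupancy is continuous across the concentration switches
        for cut in traj.segment_bounds[:-1]:
            jump = np.abs(traj.occupancies[cut] - traj.occupancies[cut - 1])
            dt = traj.times[cut] - traj.times[cut - 1]
            assert np.all(jump < 0.5 * dt * 1e4 + 1e-6)
        assert traj.times.size == 60

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationProtocol(segments=())


class TestEquilibriumCurves:
    def test_po_zero_without_ligand_and_bounded(self, fixture_rates):
        L = np.array([0.0, 0.1, 1.0, 10.0, 1000.0])
        curve = concentration_po_curve(fixture_rates, "F1", CouplingFactors(), L)
        assert curve.po[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all((curve.po >= 0) & (curve.po <= 1))
        np.testing.assert_allclose(curve.occupancies.sum(axis=1), 1.0, atol=1e-10)

    def test_saturating_po_set_by_terminal_opening(self, fixture_rates):
        """At saturation all occupancy sits in the triple-liganded branch and
        Po approaches the F3/O3/C3 equilibrium share of the open state."""
        curve = concentration_po_curve(fixture_rates, "F1", CouplingFactors(),
                                       np.array([1e6]))
        k21, k22 = fixture_rates[21], fixture_rates[22]
        E_F3 = fixture_rates[11] / fixture_rates[12]
        expected = (E_F3 * k21 / k22) / (1 + E_F3 + E_F3 * k21 / k22)
        assert curve.po[-1] == pytest.approx(expected, rel=1e-6)

    def test_binding_zero_and_saturates(self, fixture_rates):
        L = np.geomspace(1e-4, 1e6, 30)
        curve = binding_occupancy_curve(fixture_rates, "F1", CouplingFactors(), L)
        assert curve.binding[0] < 1e-3
        assert curve.binding[-1] == pytest.approx(1.0, abs=1e-3)
        # non-decreasing for the reference fixture
        assert np.all(np.diff(curve.binding) >= -1e-9)
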