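"""Analytic synchronized branches: roots, phase shifts, stability, closed-form R."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from avsync import (
    BranchDoesNotExistError,
    NetworkParams,
    UnbalancedCouplingError,
    closed_form_R,
    collective_frequencies,
    enumerate_branches,
    integrate,
    locked_initial_state,
    order_parameter,
    phase_shift_candidates,
    phase_shifts,
    stability,
    stable_branches,
    steady_state,
)
from avsync.branches import _sum_residual, fixed_point_residual


class TestCollectiveFrequencies:
    def test_zero_delay_single_root_is_mean_frequency(self, theta_params):
        roots = collective_frequencies(theta_params(0.0))
        assert len(roots) == 1
        assert roots[0] == pytest.approx(4.0, abs=1e-12)

    def test_large_delay_has_multiple_roots(self, theta_params):
        roots = collective_frequencies(theta_params(0.95))
        assert len(roots) >= 3

    @pytest.mark.parametrize("tau", [0.0, 0.07, 0.5, 0.95])
    def test_every_root_satisfies_residual(self, theta_params, tau):
        p = theta_params(tau)
        for Om in collective_frequencies(p):
            res = min(
                abs(_sum_residual(Om, p, 0)), abs(_sum_residual(Om, p, 1))
            )
            assert res < 1e-10

    def test_unbalanced_coupling_refused(self):
        p = NetworkParams(3, 4, 5, 3.0, 5.0, 0.1)
        with pytest.raises(UnbalancedCouplingError, match="numerical integration"):
            collective_frequencies(p)

    def test_empty_bracket_rejected(self, theta_params):
        with pytest.raises(ValueError, match="bracket"):
            collective_frequencies(theta_params(0.1), omega_bracket=(5.0, 5.0))


class TestPhaseShifts:
    def test_zero_delay_principal_shifts(self, theta_params):
        """At tau = 0, Omega = 4: phi1 = arcsin((4-3)/5), phi2 = 0."""
        phi1, phi2 = phase_shifts(4.0, theta_params(0.0))
        assert phi1 == pytest.approx(np.arcsin(0.2), abs=1e-12)
        assert phi2 == pytest.approx(0.0, abs=1e-12)

    def test_against_direct_solution_of_locked_equations(self, theta_params):
        """Independent oracle: solve the three locked-state equations
        numerically and compare with the arcsin expressions."""
        p = theta_params(0.07)
        (Om,) = [r for r in collective_frequencies(p) if abs(r - 3.25) < 0.1]

        def eqs(x):
            phi1, phi2 = x
            return [
                p.omega1 + p.kappa1 * np.sin(phi1) - Om,
                p.omega2 + p.kappa2 * np.sin(phi2 - Om * p.tau) - Om,
            ]

        sol = fsolve(eqs, [0.0, Om * p.tau], full_output=False)
        assert phase_shifts(Om, p) == pytest.approx(tuple(sol), abs=1e-8)

    def test_strong_coupling_limit_in_phase(self):
        """As kappa grows the locked phase shifts vanish (in-phase state)."""
        p = NetworkParams(3, 4, 5, 1e4, 1e4, 0.0)
        phi1, phi2 = phase_shifts(4.0, p)
        assert abs(phi1) < 1e-3 and abs(phi2) < 1e-3

    def test_out_of_range_frequency_raises(self, theta_params):
        p = theta_params(0.0)
        with pytest.raises(BranchDoesNotExistError):
            phase_shifts(p.omega1 + p.kappa1 + 1.0, p)

    def test_four_candidates_with_principal_first(self, theta_params):
        cands = phase_shift_candidates(4.0, theta_params(0.0))
        assert len(cands) == 4
        assert cands[0][2] == (0, 0)


class TestStability:
    def test_symmetric_in_phase_state_is_stable(self):
        """Equal frequencies, zero delay, in-phase: the Laplacian-like case
        with one structural zero mode and the rest strictly damped."""
        p = NetworkParams(4, 4, 4, 5.0, 5.0, 0.0)
        eigs, stable = stability(4.0, 0.0, 0.0, p)
        assert stable
        re = sorted(v.real for v in eigs)
        assert abs(re[-1]) < 1e-9  # structural zero
        assert re[-2] < -1e-3  # remaining modes damped

    def test_nonfixed_point_rejected(self, theta_params):
        with pytest.raises(ValueError, match="not a fixed point"):
            stability(4.0, 1.0, 1.0, theta_params(0.0))

    def test_cubic_and_spectral_agree_near_zero_delay(self, theta_params):
        """Dropping the delay exponentials is harmless at small Omega*tau."""
        p = theta_params(0.07)
        brs = enumerate_branches(p, stability_mode="spectral")
        for b in brs:
            _, cubic_verdict = stability(b.Omega, b.phi1, b.phi2, p, mode="cubic")
            assert cubic_verdict == b.stable

    def test_unknown_mode_rejected(self, theta_params):
        p = theta_params(0.0)
        with pytest.raises(ValueError, match="mode"):
            stability(4.0, np.arcsin(0.2), 0.0, p, mode="exact")


class TestClosedFormR:
    @pytest.mark.parametrize(
        "phi1,phi2,R",
        [
            (0.0, 0.0, 1.0),
            (0.0, np.pi, 1.0 / 3.0),
            (2 * np.pi / 3, 4 * np.pi / 3, 0.0),
        ],
    )
    def test_reference_values(self, phi1, phi2, R):
        assert closed_form_R(phi1, phi2) == pytest.approx(R, abs=1e-12)

    def test_matches_order_parameter_of_locked_configuration(self, rng):
        """The closed form is the order parameter of phases
        (-phi1, -phi2, 0); check against the general R computation."""
        from tests.test_metrics import _toy_trajectory

        for _ in range(10):
            phi1, phi2 = rng.uniform(-np.pi, np.pi, 2)
            series = order_parameter(_toy_trajectory([(-phi1, -phi2, 0.0)]))
            assert closed_form_R(phi1, phi2) == pytest.approx(
                series.R[0], abs=1e-12
            )


class TestStableBranches:
    def test_small_delay_high_coherence_branch(self, theta_params):
        """tau = 0.07: one stable in-phase-like branch with R = 0.9995."""
        brs = stable_branches(theta_params(0.07))
        assert len(brs) == 1
        assert brs[0].R == pytest.approx(0.9995, abs=0.005)

    def test_large_delay_partially_synchronized_branch(self, theta_params):
        """tau = 0.95: a stable branch with R = 0.3326 (V out of phase)."""
        brs = stable_branches(theta_params(0.95))
        assert any(abs(b.R - 0.3326) < 0.01 for b in brs)

    def test_all_enumerated_branches_are_fixed_points(self, theta_params):
        for b in enumerate_branches(theta_params(0.95)):
            assert fixed_point_residual(b.Omega, b.phi1, b.phi2,
                                        theta_params(0.95)) < 1e-9

    def test_zero_delay_unique_branch(self, theta_params):
        brs = enumerate_branches(theta_params(0.0))
        stable = [b for b in brs if b.stable]
        assert len(stable) == 1
        assert stable[0].Omega == pytest.approx(4.0, abs=1e-12)

    @pytest.mark.parametrize("tau", [0.07, 0.65])
    def test_seeding_at_branch_reproduces_closed_form_R(self, theta_params, tau):
        """Integrating the DDE from a stable branch's locked configuration
        (linear history at the collective frequency) stays on the branch."""
        p = theta_params(tau)
        for b in stable_branches(p):
            th0, rates = locked_initial_state(b)
            traj = integrate(p, th0, history_rates=rates)
            ss = steady_state(order_parameter(traj), traj)
            assert ss.synchronized
            assert abs(ss.R_ss - b.R) < 0.02

    def test_auditory_leads_branches_exist_and_lock(self, theta_params, rng):
        """The negative-lag equations have their own stable branch; a
        random-initial-condition run lands on one of them."""
        p = theta_params(0.3, lag_sign="auditory_leads")
        brs = stable_branches(p)
        assert brs
        traj = integrate(p, rng.uniform(0, 2 * np.pi, 3))
        ss = steady_state(order_parameter(traj), traj)
        assert ss.synchronized
        assert any(abs(ss.R_ss - b.R) < 0.02 for b in brs)
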