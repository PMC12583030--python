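"""Constrained optimal control: Pontryagin structure, shooting, Lyapunov integral."""

import numpy as np
import pytest

from neurodesync.ocp import (
    ControlProblem,
    bang_bang_input,
    chop_input,
    hamiltonian,
    hamiltonian_rhs,
    lyapunov_calc,
    optimal_u,
    solve_ocp,
    stimulus_energy,
)
from neurodesync.prc import TWO_PI, sinusoidal_prc, sniper_prc


@pytest.fixture(scope="module")
def sin_prc():
    return sinusoidal_prc(0.5)


@pytest.fixture(scope="module")
def sin_free(sin_prc):
    return solve_ocp(ControlProblem(prc=sin_prc, beta=2.0, umax=np.inf))


class TestOptimalInput:
    def test_unconstrained_extremum_at_spike(self, sin_prc):
        # Z(0)=0, Z'(0)=Zd: u = beta*Zd/2
        p = ControlProblem(prc=sin_prc, beta=2.0, umax=np.inf)
        assert optimal_u(0.0, 0.0, p) == pytest.approx(0.5)

    def test_upper_clip(self, sin_prc):
        p = ControlProblem(prc=sin_prc, beta=2.0, umax=0.35)
        assert optimal_u(0.0, 0.0, p) == pytest.approx(0.35)

    def test_lower_clip(self, sin_prc):
        p = ControlProblem(prc=sin_prc, beta=2.0, umax=0.35)
        # at theta=pi/2, Z=Zd and Z'=0, so u_tilde = -lam*Zd/2 = -0.6 at lam=2.4
        assert optimal_u(np.pi / 2, 2.4, p) == pytest.approx(-0.35)


class TestHamiltonianDynamics:
    def test_phase_velocity_is_omega_when_input_vanishes(self, sin_prc):
        p = ControlProblem(prc=sin_prc, beta=2.0, umax=np.inf)
        # at theta=pi/2 with lam=0: Z'=0 and lam*Z=0, so u=0
        dtheta, dlam = hamiltonian_rhs(np.pi / 2, 0.0, p)
        assert dtheta == pytest.approx(p.omega)
        assert dlam == pytest.approx(0.0, abs=1e-14)

    def test_costate_equation_is_minus_dH_dtheta(self, sin_prc):
        # envelope property: with u held at the pointwise optimum, the total
        # theta-derivative of H equals the partial derivative
        p = ControlProblem(prc=sin_prc, beta=2.0, umax=0.35)
        rng = np.random.default_rng(5)
        h = 1e-6
        for theta, lam in rng.uniform([-np.pi, -2], [np.pi, 2], size=(25, 2)):
            u = float(optimal_u(theta, lam, p))
            _, dlam = hamiltonian_rhs(theta, lam, p)
            dH = (hamiltonian(theta + h, lam, u, p)
                  - hamiltonian(theta - h, lam, u, p)) / (2 * h)
            assert dlam == pytest.approx(-dH, rel=1e-5, abs=1e-7)


class TestSolveOcp:
    @pytest.mark.parametrize("umax", [0.5, 0.35, 0.2, np.inf])
    def test_boundary_condition_and_clip_feasibility(self, sin_prc, umax):
        sol = solve_ocp(ControlProblem(prc=sin_prc, beta=2.0, umax=umax))
        assert abs(sol.boundary_residual) <= 1e-6
        assert sol.theta[0] == 0.0
        assert np.all(np.abs(sol.u) <= umax + 1e-12)

    def test_weak_input_resembles_scaled_prc_slope(self, sin_prc, sin_free):
        # unconstrained optimum ~ beta * Z'(omega t) / 2 in the weak regime
        approx = 2.0 * sin_prc.dZ(sin_prc.omega * sin_free.t) / 2.0
        peak = np.max(np.abs(sin_free.u))
        assert peak == pytest.approx(0.5, rel=0.05)
        assert np.max(np.abs(sin_free.u - approx)) < 0.05 * peak

    def test_weak_input_lyapunov_closed_form(self, sin_free):
        # Lambda = beta * Zd^2 / 4 for u = beta Z'(omega t)/2 (average of cos^2)
        assert sin_free.lyap_calc == pytest.approx(2.0 * 0.25 / 4.0, rel=0.05)

    def test_constrained_matches_unconstrained_when_bound_is_loose(
            self, sin_prc, sin_free):
        loose = solve_ocp(ControlProblem(prc=sin_prc, beta=2.0, umax=0.9))
        assert np.max(np.abs(loose.u - sin_free.u)) < 1e-8

    def test_lyapunov_monotone_in_umax(self, sin_prc):
        lams = [
            solve_ocp(ControlProblem(prc=sin_prc, beta=2.0, umax=u)).lyap_calc
            for u in (0.1, 0.2, 0.3, 0.4, 0.5, np.inf)
        ]
        assert all(b >= a - 1e-10 for a, b in zip(lams, lams[1:]))

    def test_energy_monotone_in_umax(self, sin_prc, sin_free):
        e = [solve_ocp(ControlProblem(prc=sin_prc, beta=2.0, umax=u)).energy
             for u in (0.2, 0.35)] + [sin_free.energy]
        assert e[0] < e[1] < e[2]

    def test_invalid_problems_rejected(self, sin_prc):
        with pytest.raises(ValueError):
            ControlProblem(prc=sin_prc, beta=-1.0)
        with pytest.raises(ValueError):
            ControlProblem(prc=sin_prc, beta=2.0, umax=-0.5)


class TestLyapunovCalc:
    def test_zero_input_gives_zero_exponent(self, sin_prc):
        t = np.linspace(0, TWO_PI, 256)
        assert lyapunov_calc(t, np.zeros_like(t), sin_prc) == 0.0

    def test_bang_bang_matches_analytic_average(self, sin_prc):
        # u = umax*sign(cos t), theta ~ t: Lambda = (Zd*umax/2pi) int |cos| = 2*umax*Zd/pi
        umax = 0.2
        t, u = bang_bang_input(sin_prc, umax=umax, n_out=8192)
        lam = lyapunov_calc(t, u, sin_prc)
        assert lam == pytest.approx(2 * umax * 0.5 / np.pi, rel=0.005)

    def test_coarse_grid_rejected(self, sin_prc):
        t = np.linspace(0, TWO_PI, 32)
        with pytest.raises(ValueError, match="coarse"):
            lyapunov_calc(t, np.zeros_like(t), sin_prc)


class TestStimulusEnergy:
    def test_constant_input(self):
        t = np.linspace(0, TWO_PI, 100)
        assert stimulus_energy(t, np.zeros_like(t)) == 0.0
        assert stimulus_energy(t, np.full_like(t, 0.3)) == pytest.approx(
            0.09 * TWO_PI)


class TestBangBang:
    def test_switch_times_at_prc_slope_zeros(self, sin_prc):
        t, u = bang_bang_input(sin_prc, umax=0.2, n_out=4096)
        switches = t[np.nonzero(np.diff(np.sign(u)))[0]]
        assert switches == pytest.approx([np.pi / 2, 3 * np.pi / 2], abs=0.01)

    def test_dominates_random_admissible_inputs(self, sin_prc):
        umax = 0.2
        t, u_bb = bang_bang_input(sin_prc, umax=umax, n_out=1024)
        lam_bb = lyapunov_calc(t, u_bb, sin_prc)
        rng = np.random.default_rng(11)
        for _ in range(50):
            # random smooth admissible input
            coeffs = rng.uniform(-1, 1, 6)
            u = sum(c * np.cos((k + 1) * t + rng.uniform(0, TWO_PI))
                    for k, c in enumerate(coeffs))
            u = umax * u / max(1e-9, np.max(np.abs(u)))
            assert lyapunov_calc(t, u, sin_prc) <= lam_bb + 1e-6

    def test_clipped_fraction_grows_with_beta(self, sin_prc):
        fracs = []
        for beta in (2.0, 20.0):
            sol = solve_ocp(ControlProblem(prc=sin_prc, beta=beta, umax=0.2))
            fracs.append(np.mean(np.abs(sol.u) >= 0.2 - 1e-9))
        assert fracs[1] > fracs[0]


class TestChopInput:
    def test_identity_when_bound_not_hit(self, sin_free):
        t, u_chop, resid = chop_input(sin_free, umax=1.0)
        np.testing.assert_array_equal(u_chop, sin_free.u)

    def test_chop_close_to_constrained_optimum_for_weak_input(
            self, sin_prc, sin_free):
        sol_c = solve_ocp(ControlProblem(prc=sin_prc, beta=2.0, umax=0.35))
        _, u_chop, resid = chop_input(sin_free, umax=0.35)
        assert np.max(np.abs(u_chop - sol_c.u)) < 0.1 * 0.35
        # chopping breaks the boundary condition only mildly here
        assert resid < 0.05


def test_sniper_constrained_solution_reference_value():
    # independent anchor for the Type I family at a binding constraint
    sol = solve_ocp(ControlProblem(prc=sniper_prc(0.5), beta=2.0, umax=0.35))
    assert sol.lyap_calc == pytest.approx(0.101, rel=0.05)
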