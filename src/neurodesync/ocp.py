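"""Magnitude-constrained optimal control of the phase-difference Lyapunov exponent.

For a pair of identical, nearly synchronized phase oscillators driven by a
common stimulus ``u``, the phase difference ``phi`` obeys
``dphi/dt = Z'(theta) u phi`` to first order, so ``phi ~ exp(Lambda t)`` with
finite-time Lyapunov exponent

    Lambda = (1/T) * int_0^T Z'(theta(s)) u(s) ds.

The stimulus is chosen to maximize ``Lambda`` while penalizing energy, via the
cost ``int_0^t1 [u^2 - beta Z'(theta) u] dt`` subject to the hard bound
``|u| <= umax``.  Pontryagin's minimum principle on the Hamiltonian

    H = u^2 - beta Z'(theta) u + lam (omega + Z(theta) u)

gives the unconstrained extremum ``u_tilde = (beta Z'(theta) - lam Z(theta))/2``
clipped to ``[-umax, umax]``, with state/co-state dynamics

    theta' = omega + Z(theta) u,
    lam'   = (beta Z''(theta) - lam Z'(theta)) u,

and boundary conditions ``theta(0) = 0``, ``theta(t1) = omega t1`` (the
stimulus must leave the oscillator's phase where the free flow would have
taken it).  The resulting two-point boundary value problem is solved by a
one-dimensional shooting method on ``lam(0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .prc import PhaseResponseCurve

__all__ = [
    "ControlProblem",
    "ControlSolution",
    "optimal_u",
    "hamiltonian",
    "hamiltonian_rhs",
    "solve_ocp",
    "lyapunov_calc",
    "stimulus_energy",
    "bang_bang_input",
    "chop_input",
    "ShootingError",
]

# The residual tolerance of the boundary condition demands a tight integrator.
_RTOL = 1e-10
_ATOL = 1e-12
_N_OUT = 4096


class ShootingError(RuntimeError):
    """Raised when the shooting method fails to bracket or converge."""


@dataclass(frozen=True)
class ControlProblem:
    """One (PRC, beta, umax, t1) optimal-control instance.

    ``beta`` weights the Lyapunov-exponent reward against the energy cost;
    ``umax`` may be ``np.inf`` for the unconstrained problem; ``t1`` defaults
    to one period of the PRC's source oscillator.
    """

    prc: PhaseResponseCurve
    beta: float
    umax: float = np.inf
    t1: Optional[float] = None

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if not self.umax > 0:
            raise ValueError("umax must be positive (np.inf for unconstrained)")
        if self.t1 is None:
            object.__setattr__(self, "t1", self.prc.T)
        if not self.t1 > 0:
            raise ValueError("t1 must be positive")

    @property
    def omega(self) -> float:
        return self.prc.omega


@dataclass
class ControlSolution:
    """Solved trajectories of a :class:`ControlProblem` on a dense grid."""

    problem: ControlProblem
    t: np.ndarray
    theta: np.ndarray
    lam: np.ndarray
    u: np.ndarray
    lambda0: float
    boundary_residual: float

    lyap_calc: float = field(init=False)
    energy: float = field(init=False)

    def __post_init__(self):
        p = self.problem
        self.lyap_calc = float(
            np.trapezoid(p.prc.dZ(self.theta) * self.u, self.t) / p.t1
        )
        self.energy = float(np.trapezoid(self.u**2, self.t))


def optimal_u(theta, lam, problem: ControlProblem):
    """Pointwise optimal input: the Hamiltonian extremum clipped to |u| <= umax."""
    prc = problem.prc
    u_tilde = 0.5 * (problem.beta * prc.dZ(theta) - np.asarray(lam) * prc.Z(theta))
    return np.clip(u_tilde, -problem.umax, problem.umax)


def hamiltonian(theta, lam, u, problem: ControlProblem):
    """Control Hamiltonian H(theta, lam, u)."""
    prc = problem.prc
    return u**2 - problem.beta * prc.dZ(theta) * u + lam * (problem.omega + prc.Z(theta) * u)


def hamiltonian_rhs(theta, lam, problem: ControlProblem):
    """State/co-state vector field with u from :func:`optimal_u`.

    Returns ``(dtheta/dt, dlam/dt)`` where ``dlam/dt = -dH/dtheta`` evaluated
    at the optimal input; both terms of the co-state equation carry the factor
    ``u``, so the co-state freezes whenever the input vanishes.
    """
    prc = problem.prc
    u = optimal_u(theta, lam, problem)
    dtheta = problem.omega + prc.Z(theta) * u
    dlam = (problem.beta * prc.d2Z(theta) - lam * prc.dZ(theta)) * u
    return dtheta, dlam


def _integrate(problem: ControlProblem, lambda0: float, t_eval=None):
    prc, beta, umax, omega = problem.prc, problem.beta, problem.umax, problem.omega

    def rhs(t, y):
        th, lam = y
        Z, dZ, d2Z = prc.eval_all(th)
        u = 0.5 * (beta * dZ - lam * Z)
        if u > umax:
            u = umax
        elif u < -umax:
            u = -umax
        return (omega + Z * u, (beta * d2Z - lam * dZ) * u)

    sol = solve_ivp(
        rhs, (0.0, problem.t1), [0.0, lambda0],
        method="DOP853", rtol=_RTOL, atol=_ATOL, t_eval=t_eval, dense_output=False,
    )
    if not sol.success:
        raise ShootingError(f"integration failed at lambda0={lambda0}: {sol.message}")
    return sol


def _shooting_residual(problem: ControlProblem, lambda0: float) -> float:
    sol = _integrate(problem, lambda0)
    return float(sol.y[0, -1] - problem.omega * problem.t1)


def solve_ocp(
    problem: ControlProblem,
    n_out: int = _N_OUT,
    lambda0_guess: float = 0.0,
    max_iter: int = 100,
    residual_tol: float = 1e-6,
) -> ControlSolution:
    """Solve the two-point boundary value problem by shooting on lam(0).

    The scalar residual ``theta(t1) - omega*t1`` is bracketed by geometric
    expansion around ``lambda0_guess`` and solved with Brent's method;
    the returned solution is deterministic for a fixed problem.

    Raises
    ------
    ShootingError
        If no sign change is found or the boundary residual exceeds
        ``residual_tol`` after convergence; the message reports the residuals
        probed as a function of lam(0).
    """
    r0 = _shooting_residual(problem, lambda0_guess)
    if abs(r0) < 1e-13:
        lo = hi = lambda0_guess
        lam_star = lambda0_guess
    else:
        # geometric bracket expansion away from the guess
        scale = max(1e-3, abs(lambda0_guess))
        probes = [(lambda0_guess, r0)]
        lam_star = None
        for i in range(max_iter):
            step = scale * 2.0**i
            for cand in (lambda0_guess - step, lambda0_guess + step):
                rc = _shooting_residual(problem, cand)
                probes.append((cand, rc))
                if np.sign(rc) != np.sign(r0):
                    lo, hi = (lambda0_guess, cand) if cand > lambda0_guess else (cand, lambda0_guess)
                    lam_star = brentq(
                        lambda l: _shooting_residual(problem, l), lo, hi,
                        xtol=1e-13, rtol=8.9e-16, maxiter=max_iter,
                    )
                    break
            if lam_star is not None:
                break
        if lam_star is None:
            raise ShootingError(
                "failed to bracket the shooting residual; probed (lambda0, residual): "
                + ", ".join(f"({l:.3g}, {r:.3g})" for l, r in probes)
            )

    t_eval = np.linspace(0.0, problem.t1, n_out)
    sol = _integrate(problem, lam_star, t_eval=t_eval)
    theta, lam = sol.y
    residual = float(theta[-1] - problem.omega * problem.t1)
    if abs(residual) > residual_tol:
        raise ShootingError(f"converged lam(0)={lam_star} but residual {residual:.3g} rad")
    u = optimal_u(theta, lam, problem)
    return ControlSolution(
        problem=problem, t=t_eval, theta=theta, lam=lam, u=np.asarray(u),
        lambda0=float(lam_star), boundary_residual=residual,
    )


def _phase_under_input(prc: PhaseResponseCurve, t: np.ndarray, u: np.ndarray):
    """Integrate dtheta/dt = omega + Z(theta) u(t) from theta(0)=0 on grid t."""
    def rhs(s, y):
        return prc.omega + prc.Z(y[0]) * np.interp(s, t, u)

    sol = solve_ivp(rhs, (t[0], t[-1]), [0.0], method="RK45",
                    rtol=1e-10, atol=1e-12, t_eval=t)
    if not sol.success:
        raise RuntimeError(f"phase integration failed: {sol.message}")
    return sol.y[0]


def lyapunov_calc(t, u, prc: PhaseResponseCurve, T: Optional[float] = None) -> float:
    """Finite-time Lyapunov exponent of a stimulus over one cycle.

    Re-integrates the phase under ``u`` from ``theta(0)=0`` and evaluates
    ``(1/T) int Z'(theta(s)) u(s) ds`` by composite trapezoidal quadrature on
    the supplied grid (at least 64 points).
    """
    t = np.asarray(t, dtype=float)
    u = np.asarray(u, dtype=float)
    if len(t) < 64:
        raise ValueError("input grid too coarse for quadrature (need >= 64 points)")
    T = prc.T if T is None else T
    theta = _phase_under_input(prc, t, u)
    return float(np.trapezoid(prc.dZ(theta) * u, t) / T)


def stimulus_energy(t, u) -> float:
    """Energy ``int u(t)^2 dt`` of a stimulus over its grid."""
    return float(np.trapezoid(np.asarray(u) ** 2, np.asarray(t)))


def bang_bang_input(prc: PhaseResponseCurve, umax: float, t1: Optional[float] = None,
                    n_out: int = _N_OUT):
    """Large-beta limit: ``u = umax * sign(Z'(omega t))``.

    Switching exactly where the PRC slope changes sign maximizes the
    Lyapunov-exponent integrand pointwise under ``|u| <= umax`` (in the weak
    input regime where ``theta ~ omega t``).
    """
    if not np.isfinite(umax):
        raise ValueError("bang-bang control requires a finite umax")
    t1 = prc.T if t1 is None else t1
    t = np.linspace(0.0, t1, n_out)
    return t, umax * np.sign(prc.dZ(prc.omega * t))


def chop_input(solution: ControlSolution, umax: float):
    """Clip an unconstrained optimal input at ``+-umax`` ("chopped" stimulus).

    Returns ``(t, u_chop, boundary_residual)`` where the residual
    ``|theta(t1) - omega t1|`` is obtained by re-integrating the phase under
    the clipped input: the chopped stimulus no longer satisfies the boundary
    condition of the true constrained optimum, and the residual quantifies by
    how much.
    """
    t = solution.t
    u_chop = np.clip(solution.u, -umax, umax)
    prc = solution.problem.prc
    theta = _phase_under_input(prc, t, u_chop)
    residual = float(abs(theta[-1] - prc.omega * t[-1]))
    return t, u_chop, residual
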