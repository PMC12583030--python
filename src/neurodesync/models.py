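"""Conductance-based neuron models: limit cycles, adjoint PRCs, isochron phases.

Two classic models are provided at a baseline current density ``Ib = 10``
(uA/cm^2), where both have a stable periodic orbit:

* ``hodgkin_huxley`` — the four-dimensional squid-axon equations (V, m, h, n)
  in the modern sign convention (C = 1 uF/cm^2, gNa = 120, gK = 36,
  gL = 0.3 mS/cm^2, ENa = 50, EK = -77, EL = -54.4 mV).
* ``reduced_hodgkin_huxley`` — the standard two-dimensional reduction
  (V, n) with the fast sodium activation slaved to voltage, m = m_inf(V),
  and the inactivation tied to the recovery variable, h = 0.8 - n.

Phase zero is placed at the voltage maximum (the spike peak).  The voltage
phase response curve is computed with the adjoint method: the co-state
z(t) of the variational equation, integrated backward along the orbit until
periodic and normalized so that <z(t), f(x(t))> = omega for all t; its
voltage component is the PRC per unit current density (C = 1 makes current
and dV/dt numerically identical).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .prc import TWO_PI

__all__ = [
    "NeuronModel",
    "LimitCycle",
    "hodgkin_huxley",
    "reduced_hodgkin_huxley",
    "find_limit_cycle",
    "compute_adjoint_prc",
    "phase_of_state",
    "phases_of_states",
    "NoLimitCycleError",
    "AdjointConvergenceError",
    "BasinEscapeError",
]

IB_DEFAULT = 10.0

# membrane parameters shared by both models (mS/cm^2, mV, uF/cm^2)
G_NA, G_K, G_L = 120.0, 36.0, 0.3
E_NA, E_K, E_L = 50.0, -77.0, -54.4
C_M = 1.0


class NoLimitCycleError(RuntimeError):
    pass


class AdjointConvergenceError(RuntimeError):
    pass


class BasinEscapeError(RuntimeError):
    pass


def _vtrap(x, scale):
    """x / (1 - exp(-x/scale)) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    xs = np.where(small, 1.0, x)  # avoid 0/0 in the masked branch
    out = np.where(small, scale + x / 2.0, xs / (1.0 - np.exp(-xs / scale)))
    return out


def _rates(V):
    am = 0.1 * _vtrap(V + 40.0, 10.0)
    bm = 4.0 * np.exp(-(V + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    an = 0.01 * _vtrap(V + 55.0, 10.0)
    bn = 0.125 * np.exp(-(V + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def _m_inf(V):
    am, bm, *_ = _rates(V)
    return am / (am + bm)


def _ionic_current(V, m, h, n):
    return (
        G_NA * m**3 * h * (V - E_NA)
        + G_K * n**4 * (V - E_K)
        + G_L * (V - E_L)
    )


def _hh_f(x, I):
    V, m, h, n = x
    am, bm, ah, bh, an, bn = _rates(V)
    dV = (I - _ionic_current(V, m, h, n)) / C_M
    return np.array([
        dV,
        am * (1.0 - m) - bm * m,
        ah * (1.0 - h) - bh * h,
        an * (1.0 - n) - bn * n,
    ])


def _rhh_f(x, I):
    V, n = x
    m = _m_inf(V)
    h = 0.8 - n
    am, bm, ah, bh, an, bn = _rates(V)
    dV = (I - _ionic_current(V, m, h, n)) / C_M
    return np.array([dV, an * (1.0 - n) - bn * n])


def _rhh_f_vec(V, n, I):
    """Vectorized Reduced HH vector field over arrays of states (population use).

    Lean path: skips the h-gate rates, which the reduction replaces by 0.8 - n.
    """
    am = 0.1 * _vtrap(V + 40.0, 10.0)
    bm = 4.0 * np.exp(-(V + 65.0) / 18.0)
    m = am / (am + bm)
    an = 0.01 * _vtrap(V + 55.0, 10.0)
    bn = 0.125 * np.exp(-(V + 65.0) / 80.0)
    dV = (I - G_NA * m**3 * (0.8 - n) * (V - E_NA)
          - G_K * n**4 * (V - E_K) - G_L * (V - E_L)) / C_M
    dn = an * (1.0 - n) - bn * n
    return dV, dn


@dataclass(frozen=True)
class NeuronModel:
    """A smooth autonomous vector field ``f(x, I)`` with baseline current Ib."""

    name: str
    state_dim: int
    f: Callable[[np.ndarray, float], np.ndarray]
    Ib: float = IB_DEFAULT
    # rest-like initial condition used to settle onto the limit cycle
    x0: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def rhs(self, t, x, I=None):
        return self.f(x, self.Ib if I is None else I)

    def jacobian(self, x, I=None, h: float = 1e-6):
        """Central finite-difference Jacobian of f at x."""
        I = self.Ib if I is None else I
        x = np.asarray(x, dtype=float)
        J = np.empty((self.state_dim, self.state_dim))
        for j in range(self.state_dim):
            dx = np.zeros_like(x)
            dx[j] = h * max(1.0, abs(x[j]))
            J[:, j] = (self.f(x + dx, I) - self.f(x - dx, I)) / (2.0 * dx[j])
        return J


def hodgkin_huxley(Ib: float = IB_DEFAULT) -> NeuronModel:
    V0 = -65.0
    am, bm, ah, bh, an, bn = _rates(V0)
    x0 = np.array([V0, am / (am + bm), ah / (ah + bh), an / (an + bn)])
    return NeuronModel(name="hh", state_dim=4, f=_hh_f, Ib=Ib, x0=x0)


def reduced_hodgkin_huxley(Ib: float = IB_DEFAULT) -> NeuronModel:
    V0 = -65.0
    _, _, _, _, an, bn = _rates(V0)
    x0 = np.array([V0, an / (an + bn)])
    return NeuronModel(name="rhh", state_dim=2, f=_rhh_f, Ib=Ib, x0=x0)


@dataclass
class LimitCycle:
    """A stable periodic orbit sampled at M uniform phases, theta = 0 at the V peak."""

    model: NeuronModel
    T: float
    thetas: np.ndarray          # 2*pi*j/M, j = 0..M-1
    samples: np.ndarray         # (M, state_dim) states at those phases
    return_residual: float      # ||Phi_T(x(0)) - x(0)||_inf

    _splines: list = field(default_factory=list, repr=False)

    @property
    def omega(self) -> float:
        return TWO_PI / self.T

    def state_at(self, theta):
        """Periodic cubic-spline interpolation of the orbit at arbitrary phase."""
        if not self._splines:
            th = np.append(self.thetas, TWO_PI)
            for j in range(self.model.state_dim):
                y = np.append(self.samples[:, j], self.samples[0, j])
                self._splines.append(CubicSpline(th, y, bc_type="periodic"))
        theta = np.mod(theta, TWO_PI)
        return np.stack([s(theta) for s in self._splines], axis=-1)


def _peak_event(model: NeuronModel):
    """Event at dV/dt = 0 crossings from above (voltage maxima)."""

    def ev(t, x):
        return model.rhs(t, x)[0]

    ev.direction = -1.0
    return ev


def find_limit_cycle(
    model: NeuronModel,
    Ib: Optional[float] = None,
    transient: float = 500.0,
    M: int = 1024,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_residual: float = 1e-6,
) -> LimitCycle:
    """Settle onto the stable periodic orbit and sample it at M uniform phases.

    The trajectory is integrated past a ``transient`` (ms); the period is the
    interval between successive voltage maxima (located by the integrator's
    event machinery on dV/dt = 0 with V above 0 mV).  The orbit is then
    resampled over one period starting at the peak.

    Raises
    ------
    NoLimitCycleError
        If no suprathreshold voltage maxima are found within the search window.
    """
    if Ib is not None:
        model = NeuronModel(name=model.name, state_dim=model.state_dim,
                            f=model.f, Ib=Ib, x0=model.x0)
    ev = _peak_event(model)
    sol = solve_ivp(model.rhs, (0.0, transient + 200.0), model.x0,
                    method="RK45", rtol=rtol, atol=atol, events=ev)
    t_ev = sol.t_events[0]
    x_ev = sol.y_events[0]
    keep = (t_ev > transient) & (x_ev[:, 0] > 0.0) if len(t_ev) else np.zeros(0, bool)
    if keep.sum() < 3:
        raise NoLimitCycleError(
            f"no sustained spiking found for {model.name} at Ib={model.Ib}")
    t_pk = t_ev[keep]
    x_pk = x_ev[keep]
    T = float(t_pk[-1] - t_pk[-2])
    x_start = x_pk[-1]

    # one clean period from the (converged) peak state, sampled uniformly
    phases_t = np.linspace(0.0, T, M, endpoint=False)
    sol2 = solve_ivp(model.rhs, (0.0, T), x_start, method="RK45",
                     rtol=rtol, atol=atol, t_eval=np.append(phases_t, T))
    samples = sol2.y[:, :-1].T
    residual = float(np.max(np.abs(sol2.y[:, -1] - x_start)))
    if residual > max_residual:
        raise NoLimitCycleError(
            f"orbit failed to close: return residual {residual:.3g} for {model.name}")
    thetas = TWO_PI * np.arange(M) / M
    return LimitCycle(model=model, T=T, thetas=thetas, samples=samples,
                      return_residual=residual)


def compute_adjoint_prc(
    model: NeuronModel,
    lc: LimitCycle,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    polish_periods: int = 2,
    norm_tol: float = 1e-4,
):
    """Voltage phase response curve via the periodic solution of the adjoint equation.

    The adjoint (variational-transpose) equation ``dz/dt = -J(x(t))^T z`` is
    integrated backward in time along the stored orbit (interpolated with
    periodic splines).  Its one-period backward map B is built by integrating
    the matrix fundamental solution; the periodic adjoint is the eigenvector
    of B with unit eigenvalue (the phase-neutral Floquet mode; the remaining
    eigenvalues are the reciprocal contraction multipliers, < 1 backward).
    The eigenvector is polished by a few further backward periods — backward
    integration damps any residual transverse component — and scaled so that
    ``<z(theta), f(x(theta))> = omega`` everywhere, which the continuous
    dynamics conserve exactly.

    Returns
    -------
    (thetas, Z_V, Z_full):
        Phase grid, voltage-component PRC samples (per unit current density),
        and the full adjoint vectors (M, state_dim).

    Raises
    ------
    AdjointConvergenceError
        If B has no eigenvalue near 1 or the normalization identity is
        violated beyond ``norm_tol`` relatively.
    """
    T, omega, M = lc.T, lc.omega, len(lc.thetas)
    d = model.state_dim

    def rhs_mat(t, zflat):
        x = lc.state_at(omega * t)
        mJT = -model.jacobian(x).T
        return (mJT @ zflat.reshape(d, d)).ravel()

    sol = solve_ivp(rhs_mat, (T, 0.0), np.eye(d).ravel(), method="RK45",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise AdjointConvergenceError(sol.message)
    B = sol.y[:, -1].reshape(d, d)  # backward one-period map z(T) -> z(0)
    evals, evecs = np.linalg.eig(B)
    i1 = int(np.argmin(np.abs(evals - 1.0)))
    if abs(evals[i1] - 1.0) > 0.05 or abs(evals[i1].imag) > 1e-6:
        raise AdjointConvergenceError(
            f"no unit Floquet eigenvalue in backward adjoint map: {evals}")
    z = np.real(evecs[:, i1])

    def rhs(t, z):
        x = lc.state_at(omega * t)
        return -model.jacobian(x).T @ z

    t_grid = np.linspace(0.0, T, M, endpoint=False)
    profile = None
    for _ in range(polish_periods):
        sol = solve_ivp(rhs, (T, 0.0), z, method="RK45", rtol=rtol, atol=atol,
                        t_eval=t_grid[::-1])
        if not sol.success:
            raise AdjointConvergenceError(sol.message)
        profile = sol.y[:, ::-1].T      # (M, dim), increasing t
        z = profile[0].copy()           # z(T) = z(0) by periodicity

    f_grid = np.array([model.rhs(0.0, lc.samples[j]) for j in range(M)])
    dots = np.einsum("ij,ij->i", profile, f_grid)
    scale = omega / dots[0]
    profile = profile * scale
    dots = dots * scale
    rel_err = float(np.max(np.abs(dots - omega)) / omega)
    if rel_err > norm_tol:
        raise AdjointConvergenceError(
            f"adjoint normalization identity violated: rel err {rel_err:.2e}")

    Z_full = profile
    Z_V = Z_full[:, 0] / C_M
    return lc.thetas.copy(), Z_V, Z_full


def phase_of_state(model: NeuronModel, lc: LimitCycle, state, rtol: float = 1e-8,
                   atol: float = 1e-10) -> float:
    """Isochron phase of an arbitrary state in the basin of the limit cycle.

    Integrates the unperturbed model until the next spike (voltage maximum
    above 0 mV) at time ts and returns ``theta = 2*pi*(1 - ts/T)`` wrapped to
    [0, 2*pi): a state that spikes immediately has phase ~0 (= 2*pi).
    """
    ev = _peak_event(model)
    state = np.asarray(state, dtype=float)
    t0 = 0.0
    for _ in range(3):  # restart past subthreshold maxima if needed
        sol = solve_ivp(model.rhs, (t0, t0 + 5.0 * lc.T), state, method="RK45",
                        rtol=rtol, atol=atol, events=ev)
        t_ev, x_ev = sol.t_events[0], sol.y_events[0]
        supra = [i for i in range(len(t_ev)) if x_ev[i][0] > 0.0 and t_ev[i] > t0 + 1e-9]
        if supra:
            ts = float(t_ev[supra[0]])
            return float(np.mod(TWO_PI * (1.0 - ts / lc.T), TWO_PI))
        state = sol.y[:, -1]
        t0 = float(sol.t[-1])
    raise BasinEscapeError("no suprathreshold spike within 5 periods of the state")


def phases_of_states(model: NeuronModel, lc: LimitCycle, V, n, dt: float = 0.01,
                     horizon_periods: float = 5.0, on_fail: str = "raise"):
    """Vectorized isochron phases for many 2-D (V, n) states at once.

    Fixed-step RK4 integration of the noise-free, uncoupled Reduced HH
    equations for all states simultaneously; the first suprathreshold voltage
    maximum of each trajectory is located on the step grid and refined by
    quadratic interpolation.  Accuracy is O(dt^2) in the spike time, ample
    for order-parameter estimation.

    States that produce no spike within ``horizon_periods`` either raise
    :class:`BasinEscapeError` (``on_fail="raise"``) or come back as NaN
    (``on_fail="nan"``) for the caller to exclude.
    """
    if model.state_dim != 2:
        raise ValueError("phases_of_states supports 2-D (V, n) models")
    V = np.array(V, dtype=float)
    n = np.array(n, dtype=float)
    N = len(V)
    ts = np.full(N, np.nan)
    done = np.zeros(N, dtype=bool)
    V_prev2 = np.full(N, -np.inf)
    V_prev1 = V.copy()
    steps = int(np.ceil(horizon_periods * lc.T / dt))
    I = model.Ib

    def f(V, n):
        return _rhh_f_vec(V, n, I)

    for k in range(1, steps + 1):
        k1V, k1n = f(V, n)
        k2V, k2n = f(V + 0.5 * dt * k1V, n + 0.5 * dt * k1n)
        k3V, k3n = f(V + 0.5 * dt * k2V, n + 0.5 * dt * k2n)
        k4V, k4n = f(V + dt * k3V, n + dt * k3n)
        V = V + dt / 6.0 * (k1V + 2 * k2V + 2 * k3V + k4V)
        n = n + dt / 6.0 * (k1n + 2 * k2n + 2 * k3n + k4n)
        # local max at the previous step: V[k-2] < V[k-1] > V[k], above 0 mV
        is_peak = (~done) & (V_prev1 > V_prev2) & (V_prev1 >= V) & (V_prev1 > 0.0) & (k >= 2)
        if np.any(is_peak):
            a = V_prev2[is_peak]
            b = V_prev1[is_peak]
            c = V[is_peak]
            denom = a - 2 * b + c
            offset = np.where(np.abs(denom) > 1e-12, 0.5 * (a - c) / denom, 0.0)
            ts[is_peak] = ((k - 1) + offset) * dt
            done[is_peak] = True
        if done.all():
            break
        V_prev2, V_prev1 = V_prev1, V.copy()
    if not done.all():
        if on_fail == "raise":
            raise BasinEscapeError(
                f"{int((~done).sum())} states produced no spike within the horizon")
        # on_fail == "nan": leave the failures as NaN for the caller to handle
    return np.mod(TWO_PI * (1.0 - ts / lc.T), TWO_PI)
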