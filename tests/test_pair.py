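"""Event-triggered pair simulations and Lyapunov-exponent fitting."""

import numpy as np
import pytest

from neurodesync.ocp import ControlProblem, solve_ocp
from neurodesync.pair import (
    FitWindowError,
    PairSimConfig,
    PairSimResult,
    fit_lyapunov,
    simulate_pair,
)
from neurodesync.prc import TWO_PI, sinusoidal_prc


@pytest.fixture(scope="module")
def sin_prc():
    return sinusoidal_prc(0.5)


@pytest.fixture(scope="module")
def sin_sol(sin_prc):
    return solve_ocp(ControlProblem(prc=sin_prc, beta=2.0, umax=0.35))


def _synthetic_exponential(lam=0.1, phi0=0.1, T=TWO_PI, n_cycles=10):
    t = np.linspace(0, n_cycles * T, 2000)
    prc = sinusoidal_prc(0.5)
    theta1 = prc.omega * t
    return PairSimResult(
        config=None, t=t, theta1=theta1, theta2=theta1 + phi0 * np.exp(lam * t),
        event_times=np.arange(n_cycles) * T,
    )


class TestSimulatePair:
    def test_zero_input_freezes_phase_difference(self, sin_prc):
        t = np.linspace(0, TWO_PI, 128)
        cfg = PairSimConfig(prc=sin_prc, u_t=t, u=np.zeros_like(t), phi0=0.1)
        res = simulate_pair(cfg)
        np.testing.assert_allclose(res.phi, 0.1, atol=1e-8)

    def test_phase_difference_grows_cycle_over_cycle(self, sin_prc, sin_sol):
        res = simulate_pair(PairSimConfig(prc=sin_prc, u_t=sin_sol.t,
                                          u=sin_sol.u, phi0=0.1))
        phi_ev = np.interp(res.event_times, res.t, res.phi)
        growth_regime = phi_ev[phi_ev < 1.0]
        assert np.all(np.diff(growth_regime) > 0)

    def test_events_strictly_increasing_and_initial_offset(self, sin_prc, sin_sol):
        res = simulate_pair(PairSimConfig(prc=sin_prc, u_t=sin_sol.t,
                                          u=sin_sol.u, phi0=0.1))
        assert res.phi[0] == pytest.approx(0.1)
        assert np.all(np.diff(res.event_times) > 0)
        assert len(res.event_times) == 10

    def test_deep_linear_regime_growth_matches_integral_exponent(
            self, sin_prc, sin_sol):
        cfg = PairSimConfig(prc=sin_prc, u_t=sin_sol.t, u=sin_sol.u,
                            phi0=1e-4, n_cycles=2)
        res = simulate_pair(cfg)
        phi_end = np.interp(res.event_times[1], res.t, res.phi)
        ratio = phi_end / 1e-4
        expected = np.exp(sin_sol.lyap_calc * TWO_PI)
        assert ratio == pytest.approx(expected, rel=0.02)

    def test_invalid_configs_rejected(self, sin_prc):
        t = np.linspace(0, TWO_PI, 64)
        with pytest.raises(ValueError):
            PairSimConfig(prc=sin_prc, u_t=t, u=np.zeros_like(t), phi0=4.0)
        with pytest.raises(ValueError):
            PairSimConfig(prc=sin_prc, u_t=t, u=np.zeros(10), phi0=0.1)


class TestFitLyapunov:
    def test_recovers_exact_exponential(self):
        res = _synthetic_exponential(lam=0.1)
        lam, r2 = fit_lyapunov(res, phi_max=np.inf, sampling="dense")
        assert lam == pytest.approx(0.1, abs=1e-8)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        # cycle sampling interpolates phi at event times: same slope to 1e-6
        lam_c, _ = fit_lyapunov(res, phi_max=np.inf, sampling="cycles")
        assert lam_c == pytest.approx(0.1, abs=1e-6)

    def test_fitted_exponent_tracks_integral_exponent(self, sin_prc, sin_sol):
        res = simulate_pair(PairSimConfig(prc=sin_prc, u_t=sin_sol.t,
                                          u=sin_sol.u, phi0=0.1))
        lam_fit, _ = fit_lyapunov(res)
        assert lam_fit == pytest.approx(sin_sol.lyap_calc, rel=0.15)

    def test_saturation_reduces_dense_full_window_quality(self, sin_prc, sin_sol):
        # log phi bends once phi is order one: the guarded window fits better
        res = simulate_pair(PairSimConfig(prc=sin_prc, u_t=sin_sol.t,
                                          u=sin_sol.u, phi0=0.1, n_cycles=12))
        _, r2_guarded = fit_lyapunov(res, sampling="dense")
        _, r2_full = fit_lyapunov(res, window_fraction=1.0, phi_max=np.inf,
                                  sampling="dense")
        assert r2_guarded > r2_full

    def test_frequency_detuning_gives_linear_not_exponential_growth(self):
        # detuned but unstimulated oscillators drift apart linearly; the log
        # trace is then concave, unlike genuine exponential divergence
        from scipy.stats import linregress

        t = np.linspace(0, 20 * TWO_PI, 4000)
        phi = 0.1 + 0.01 * t
        res = PairSimResult(config=None, t=t, theta1=t, theta2=t + phi,
                            event_times=np.arange(20) * TWO_PI)
        _, r2_log = fit_lyapunov(res, window_fraction=1.0, phi_max=np.inf,
                                 sampling="dense")
        r2_linear = linregress(t, phi).rvalue ** 2
        assert r2_linear > r2_log
        # local slope of log phi decays strongly over the run
        early, _ = fit_lyapunov(res, window_fraction=0.25, phi_max=np.inf,
                                sampling="dense")
        late = (np.log(phi[-1]) - np.log(phi[len(t) // 2])) / (t[-1] - t[len(t) // 2])
        assert late < 0.5 * early

    def test_zero_crossing_rejected(self):
        t = np.linspace(0, TWO_PI * 4, 500)
        res = PairSimResult(config=None, t=t, theta1=t,
                            theta2=t + 0.1 - 0.3 * t / t[-1],
                            event_times=np.array([0.0, TWO_PI, 2 * TWO_PI]))
        for sampling in ("cycles", "dense"):
            with pytest.raises(FitWindowError):
                fit_lyapunov(res, sampling=sampling)
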