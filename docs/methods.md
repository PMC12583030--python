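# Methods

This note records the models, numerical procedures, and design choices
behind `neurodesync`, in the spirit of the methods documentation of packages
like msprime or statsmodels: enough detail to reproduce or audit every
number the code can produce.

## Phase reduction and the control objective

A neuron with a stable limit cycle of period `T` is reduced to a phase
`θ ∈ [0, 2π)` advancing at `ω = 2π/T`, with an input `u(t)` entering through
the infinitesimal phase response curve `Z(θ)`: `θ̇ = ω + Z(θ)u`. The phase
origin `θ = 0` is the spike (for the conductance models, the voltage
maximum). For two identical oscillators receiving the same input, the phase
difference `φ` obeys `φ̇ = Z'(θ)uφ + O(φ²)`, giving exponential growth at
the finite-time Lyapunov exponent `Λ = (1/T)∫₀ᵀ Z'(θ(s))u(s) ds`. Positive
`Λ` is the desynchronization objective.

The stimulus is chosen to minimize `∫₀^{t₁}[u² − βZ'(θ)u]dt` subject to
`|u| ≤ u_max`, with `t₁ = T` (one stimulus cycle per natural period;
exposed as a parameter but defaulted). `β > 0` (units: input²·time, scale
set by the PRC in use) weights desynchronization against energy; the
examples use `β = 2` for the sinusoidal, SNIPER, and Hodgkin–Huxley PRCs
and `β = 9` for the Reduced Hodgkin–Huxley PRC, whose optimal inputs are
otherwise weak relative to its sharp PRC.

Pontryagin's minimum principle on `H = u² − βZ'u + λ(ω + Zu)` yields the
pointwise optimum `ũ = (βZ' − λZ)/2` clipped to `[−u_max, u_max]`, and the
state/co-state system

    θ̇ = ω + Z(θ)u,      λ̇ = −∂H/∂θ = (βZ''(θ) − λZ'(θ)) u ,

with boundary conditions `θ(0) = 0`, `θ(t₁) = ωt₁`. Note that *both* terms
of the co-state equation carry the factor `u`; a finite-difference test of
`−∂H/∂θ` pins the form (see `tests/test_ocp.py`). The clipped `u` feeds
both equations at every integrator evaluation, so the trajectories are
those of the constrained control — that is the substantive content of the
minimum principle under an input bound.

### Shooting solver

The boundary-value problem is solved by a scalar shooting method on
`λ(0)`: the residual `r(λ₀) = θ(t₁) − ωt₁` is bracketed by geometric
expansion around `λ₀ = 0` (in the weak-input regime `βZ'` dominates `λZ`,
so zero is a natural center) and solved with Brent's method to machine
precision; a converged solution must satisfy `|r| ≤ 1e-6` rad. Integration
uses DOP853 with `rtol = 1e-10`, `atol = 1e-12`; the clip non-smoothness is
only a derivative discontinuity of the right-hand side and is handled by
the adaptive step controller (tolerance-tightening changes `Λ_calc` at the
1e-8 level). Solutions are reported on a uniform 4096-point grid; `Λ_calc`
and the energy `∫u*²dt` are composite-trapezoid quadratures on that grid.

The "chopped" input `clip(ũ, ±u_max)` of the *unconstrained* solution is
provided for comparison (`chop_input`); it violates the boundary condition
by an amount the function reports, which is how the package quantifies when
chopping is and is not a good approximation to the true constrained
optimum.

## Conductance models

The Hodgkin–Huxley equations use the modern sign convention with
`C = 1 µF/cm²`, `g_Na = 120`, `g_K = 36`, `g_L = 0.3 mS/cm²`, `E_Na = 50`,
`E_K = −77`, `E_L = −54.4 mV`, and the classic rate functions; the Reduced
model slaves sodium activation to voltage (`m = m_∞(V)`) and ties
inactivation to the recovery variable (`h = 0.8 − n`). Both are run at
baseline current `I_b = 10 µA/cm²`, where they spike tonically.

Limit cycles are located by integrating past a 500 ms transient and
measuring the interval between successive voltage maxima (integrator event
detection on `dV/dt = 0`, downward, with `V > 0 mV` to exclude subthreshold
maxima); the orbit is resampled at `M` uniform phases from the peak and
must close to `1e-6` in sup norm. Measured periods: `T = 14.6383 ms` (HH)
and `T = 11.8463 ms` (Reduced HH), stable to `< 1e-4 ms` under 10×
tolerance tightening. `M = 1024` suffices for the HH phase grid; the
Reduced HH adjoint has a sharp feature near the spike and uses `M = 4096`.

### Adjoint PRCs

The voltage PRC is the first component of the periodic solution `z(t)` of
the adjoint equation `ż = −J(x(t))ᵀz` normalized by `⟨z(t), f(x(t))⟩ = ω`.
The orbit is interpolated with periodic cubic splines; the one-period
*backward* fundamental matrix of the adjoint equation is integrated, the
periodic solution extracted as its unit-eigenvalue eigenvector (the other
eigenvalues are the reciprocal Floquet contraction factors), then polished
by two further backward periods. Backward iteration alone converges slowly
here because one Floquet mode of the Reduced HH cycle is only weakly
contracting; the eigenvector start sidesteps that. The conservation of
`⟨z, f⟩` is verified pointwise to `1e-4·ω`. Jacobians are central finite
differences (step `1e-6`, scaled); an independent finite-perturbation test
(impulse of area `1e-3` on `V`, phase shift measured by re-integration)
agrees with the adjoint PRC to 2%.

The sampled PRCs are compressed by ordinary least squares onto
`a₀ + Σ(a_k cos kθ + b_k sin kθ)` — 10 harmonics for HH, 200 for Reduced HH
(the sharp feature needs them) — with RMS residual below 2% of the PRC
amplitude; derivatives `Z'`, `Z''` needed by the control equations are
term-wise exact.

### Isochron phases

The phase of an arbitrary state is computed by integrating the unperturbed
model to its next spike at time `t_s` and setting `θ = 2π(1 − t_s/T)`. For
population snapshots this is done for all neurons at once with fixed-step
RK4 (`dt = 0.01 ms`), spike times refined by quadratic interpolation of the
three samples around each voltage maximum; batched and event-based
estimates agree to `5e-3` rad.

## Pair validation

Two phase oscillators start at `θ₁ = 0`, `θ₂ = φ₀` and receive the solved
stimulus cycle; a new cycle is triggered when `θ₁` crosses a multiple of
`2π` *after* the previous cycle has fully elapsed, for 10 cycles. Because a
converged stimulus returns `θ₁` to a multiple of `2π` within `1e-6` rad,
whether the crossing lands a hair before or after the cycle end is
integrator noise; crossings within `1e-4` rad retrigger immediately.
`φ₀ = 0.1` for the sinusoidal, SNIPER, and HH examples and `0.001` for the
Reduced HH, whose much larger `ΛT` per cycle would otherwise saturate
immediately.

`Λ_fit` is the least-squares slope of `log φ` versus `t` over the first
half of the run, restricted to samples with `φ < 1` rad: the exponent is
defined by the small-`φ` linearization, whose relative error is `O(φ)`, and
including order-one `φ` visibly bends the trace and biases the slope down.
By default the regression uses `φ` sampled at the stimulus-cycle start
times (a Poincaré section): within a cycle the growth of `φ` is
concentrated at the phases where `Z'(θ)u` is large, so for sharply peaked
PRCs `log φ(t)` is a staircase whose intra-cycle shape contaminates a
dense-in-time fit; per-cycle sampling isolates the multiplier. Dense
sampling remains available (`sampling="dense"`). With these choices
`Λ_fit` matches `Λ_calc` to ~13% or better across all built-in examples,
with the discrepancy largest where saturation limits the usable window.

## Population validation

`N = 100` Reduced HH neurons are coupled all-to-all through voltage
differences, `(α/N)Σ(V_j − V_i) = α(V̄ − V_i)` with `α = 0.04 /ms`, receive
a common input, and independent white voltage noise of intensity
`√(2D)`, `D = 0.7 mV²/ms` — a balance where coupling wins and the
uncontrolled population stays synchronized. All neurons start at the
spike-peak state. Event-based control applies one full cycle of the
precomputed `β = 9` stimulus whenever the mean voltage `V̄` crosses
`−30 mV` upward and no cycle is already active.

Numerics: fixed step `dt = 0.01 ms`; the drift (including coupling and
input) is advanced with Heun's predictor–corrector and the noise increment
`√(2D·dt)·N(0,1)` is added after the corrector — strong order 1 for
additive noise, like Euler–Maruyama, but second-order in the drift, which
keeps spike timing accurate enough that halving `dt` changes the noise-free
mean-voltage trace by well under 1 mV RMS. (A literal per-step reading
`√(2D)·N(0,1)·dt` of the noise term is available as
`noise_convention="literal"` for sensitivity checks.) Each run is fully
determined by one integer seed; noise variates are drawn in fixed-size
blocks for speed without affecting the stream. Traces are recorded at
0.1 ms; the spike raster marks suprathreshold (V > 0 mV) voltage maxima,
their times refined by quadratic interpolation on the step grid.
Synchrony is the Kuramoto order parameter `R = |N⁻¹Σe^{iθ_j}|` of the
isochron phases, sampled every 10 ms.

Validation sizes: behavioral claims are asserted over 20 matched seeds
(control on/off comparisons of time-averaged `R`) and 25 replicates per
constraint level for the mean-energy trend — the package's standard sizes
for stochastic checks, chosen to make sampling error small relative to the
effects being asserted (the on/off gap in mean `R` is ~0.2 against
replicate scatter of a few hundredths).

## Synthetic-data scope

The package generates all of its own inputs: the "data" are model
simulations under the stated parameters. The pair and population layers
emulate idealized preparations — identical neurons, identical electrode
distance (common `u`), purely electrotonic homogeneous coupling, stationary
Gaussian white noise, and noise-free phase reads for `R`. Real recordings
violate all of these (heterogeneous cells and coupling, synaptic dynamics,
measurement noise, PRCs known only approximately), so passing tests
demonstrate internal correctness of the method and its claimed parameter
trends, not clinical efficacy.

## Known limitations

* The optimal stimuli are not charge-balanced (`∫u dt ≠ 0`); enforcing
  charge balance alongside the magnitude bound enlarges the boundary-value
  problem and is not implemented.
* Single common input only; no multi-electrode or heterogeneous-delivery
  variants.
* The shooting solver assumes the scalar residual brackets a root near
  `λ₀ = 0`; at very large `β` (deep bang-bang regime) convergence can
  require the bracket expansion to run far, and failures are reported with
  the probed residuals rather than recovered automatically.
* `phases_of_states` supports the two-dimensional reduced model only; the
  event-based `phase_of_state` works for any model.
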