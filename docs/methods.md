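# Methods

## The model

A population of `N` thalamic (VPM) whisking neurons drives a single
layer-4 inhibitory (L4I) neuron through plastic feed-forward synapses.
Thalamic spiking is an inhomogeneous Poisson process with rate
`D(1 + γ cos(νt − φ_k))`: `D` is the cycle-averaged rate (spikes/s), `γ`
the modulation depth, `ν` the angular whisking frequency (rad/s), `φ_k`
the neuron's preferred phase.  Preferred phases follow a von Mises
density with concentration `κ_VPM` and mean `ψ_VPM`.  The downstream
neuron is linear-Poisson: rate `(1/N) Σ w_k ρ_k(t − d)` with weights
`w_k ∈ [0,1]` and a fixed conduction delay `d`.  Its rhythmic tuning is
determined entirely by the circular order parameters of the weight
profile — the mean `w̄` and the first circular Fourier component
`w̃ e^{iψ}` — giving mean rate `D w̄`, modulation `γ w̃/w̄`, and
preferred phase `ψ + νd`.

Plasticity is pairwise additive STDP: each pre/post pair at lag
`Δt = t_post − t_pre` contributes
`Δw = λ[f₊(w)K₊(Δt) − f₋(w)K₋(Δt)]` with soft weight bounds
`f₊ = (1−w)^μ`, `f₋ = α w^μ` and unit-area kernels.  Two kernel families
are implemented: temporally asymmetric one-sided exponentials (causal
potentiation, anti-causal depression; timescales `τ₊`, `τ₋`) and
temporally symmetric zero-mean Gaussians.  The lag `Δt = 0` is assigned
to neither branch; it is measure-zero for continuous-time spikes and the
convention avoids double counting.

## Mean-field flow

In the slow-learning limit the weight dynamics average over spike noise
and become deterministic.  In rescaled time `s = λt` each synapse obeys

    dw/ds = F_d + w̄ F₀ + w̃ F₁ ,

where `F_d = w (D/N)(f₊K₊(d) − f₋K₋(d))` is the O(1/N) contribution of
a synapse's own delayed spike echo, `F₀ = D²(f₊ − f₋)` is the
phase-blind competition between potentiation and depression (the kernel
areas are 1), and `F₁` carries the rhythm through the kernel Fourier
components `K̃± e^{iΩ±}` evaluated at `ν`:
`F₁ = D²(γ²/2)(K̃₊ f₊ cos[φ − Ω₊ − νd − ψ] − K̃₋ f₋ cos[φ − Ω₋ − νd − ψ])`.
Because only `K̃±(ν)` enters, high whisking frequencies are invisible to
the rule — algebraically suppressed for the discontinuous asymmetric
kernel, super-algebraically for the smooth Gaussian one — and the flow
collapses onto the uniform balance point `w* = (1 + α^{1/μ})^{-1}`.

The flow is integrated with the explicit Euler method, step `dt = 0.1`
in the integrator's time variable with the learning rate folded in
(`Δw = λ·dt·RHS`), weights clamped to [0,1] after every step.  Neither
`λ` nor `dt` carries stated physical units anywhere the model is
defined; all distribution-level results are invariant to the joint
rescaling `λ → cλ, dt → dt/c` (a pure relabelling of time), and a test
guards this.  Clamping is a numerical guard only: for `μ > 0` the
interior is attracting.  The self term `F_d` is included by default
(finite N); `include_self_term=False` selects the strict continuum
limit.  At the default operating point the integration is insensitive to
halving the step (final order parameters move < 1e-3).

Initial weights are not specified by the model; the default is i.i.d.
uniform(0.3, 0.7) with a recorded seed.  Limit-cycle statistics are
initialisation-independent once the transient (first 50% of a run by
default) is discarded.

## Phase placement

Two ways of realising the upstream phase distribution are provided.
Quantile placement puts `φ_k` at the k/N quantiles of the von Mises CDF
(bisection on the numerically integrated density, tolerance 1e-10) — a
deterministic population with no quenched disorder, and the default.
Accept-reject sampling draws i.i.d. phases (uniform proposal, envelope
`e^κ/(2πI₀(κ))`) for studies of quenched variability.  Because the
weight profile is periodic on the circle, the quantile-placed discrete
order-parameter sums converge to the continuum integrals at spectral
accuracy, which is what makes the N=150 default an excellent proxy for
the continuum flow.

## Fixed points

Setting the continuum flow to zero yields the stationary profile
`w*(φ) = (1 + α^{1/μ}((1+X₋)/(1+X₊))^{1/μ})^{-1}` with
`X± = (w̃/w̄)(γ²/2)K̃± cos(φ − νd − Ω± − ψ)` — an implicit problem,
since (w̄, w̃, ψ) are moments of `w*` itself.  The solver iterates
guess → profile → moments with damping 0.5 (ψ updated by circular
interpolation to avoid 2π jumps), moments computed by trapezoid
quadrature against the upstream density on a 512-point uniform phase
grid (periodic integrand, so spectrally accurate).  Convergence demands
order-parameter movement below 1e-10, at which point the continuum
residual max|dw/ds| is at the 1e-9 scale.  The solver establishes
existence only; stability is assessed by integrating the flow from a
perturbed solution.  Both residuals — with and without the O(1/N) self
term — are reported, because at N ≈ 150 the self term shifts the finite-N
equilibrium visibly (w̄ by ~0.04 at μ = 0.1) and comparisons against the
analytic profile are only meaningful in the continuum.

## Event-level validation

The spiking simulator realises the exact generative model: thinning
against the bound `D(1+γ)` for thalamic trains, per-spike thinning with
probability `w_k/N` (delayed by `d`) for the downstream train, and the
pairwise update applied to every pre/post pair within
`10·max(τ₊, τ₋)` (kernel mass beyond is < 5e-5).  Weights are frozen
over batches of many whisking cycles (default 50) and updates are
accumulated at the pre-batch weights — valid to first order in `λ`,
which is the regime the mean-field derivation assumes.  A frozen-state
check (expected one-batch weight change vs. `λ·T·RHS` over repeated
realisations) confirms the simulator is statistically unbiased.

A genuine limitation, documented deliberately: at `λ = 1e-3` with the
default kernels the per-pair weight kicks reach `λ/τ₊ ≈ 0.045`, and the
full stochastic dynamics sit measurably away from the deterministic
limit cycle (w̄ high by ~0.1 at the headline operating point) — noise is
rectified at the `w = 0` boundary where depression vanishes
(`f₋(0) = 0`), and the nearly additive rule (`μ = 0.01`) makes the flow
multistable, so stochastic and deterministic paths can settle into
different behaviour.  The discrepancy shrinks roughly linearly in `λ`
(w̄ agrees to 1% at `λ = 1e-4`), but the Monte-Carlo standard error of
seed-averaged statistics shrinks like `√λ` at matched rescaled duration,
so a fixed z-score criterion does not become easier at smaller `λ`.
Agreement should be judged at the few-percent level in the slow-learning
regime, not against seed noise.

## Circular statistics

The downstream preferred phase `ψ_L4I(t) = ψ(t) + νd` is unwrapped
(records with `w̃ < 1e-12` are excluded; consecutive wrapped steps must
stay below π/4 or the cadence is refused), differentiated by central
differences for the drift velocity, and accumulated into a time-weighted
occupancy histogram (36 bins of 10° by default) over whole drift
revolutions only — partial cycles bias the histogram, and at least three
full revolutions are required.  Because occupancy along a periodic orbit
is proportional to inverse speed, the histogram is cross-checked against
`1/|dψ/dt|`.

Von Mises fitting defaults to maximum likelihood: mean direction from
the resultant vector, concentration by inverting
`R̄ = I₁(κ)/I₀(κ)` (bracketed root find, tolerance 1e-8, `R̄ = 0 → κ = 0`).
A nonlinear-least-squares fit of the density curve to the binned
histogram is selectable (`fit_mode="nls"`) for parity with
curve-fitting-based workflows; on the headline run ML gives κ ≈ 0.99 and
NLS κ ≈ 1.15 — the fitted concentration is fit-method and binning
dependent at the ±0.2 level, the mean direction is not.  Fits whose
sup-distance to the histogram exceeds 0.2 are flagged: near `μ ≈ 0.07`
the occupancy is bimodal and a single von Mises is knowingly
misspecified.

## Pooling baseline

The plasticity-free null model pools `N` i.i.d. upstream phases with
equal ("uniform") or i.i.d. uniform(0,1) ("random") weights — the random
weight law is a modelling choice, configurable — and records the phase
of the summed rate, `arg Σ w_k e^{iφ_k}` plus the delay lag.  Across
repetitions this quenched ensemble sharpens indefinitely with `N` and
its mean stays locked to `ψ_VPM + νd`, which is exactly what the drift
mechanism is contrasted against.

## Problem sizes and defaults

Headline runs integrate 200,000 Euler steps (N = 150), enough for ~250
drift revolutions, of which the second half is analysed; sweep runs use
150,000 steps.  The event-level comparison uses N = 50 and 12,000 s of
simulated time per seed.  The fixed-point grid is 512 points.  These
sizes make every result reproducible on a laptop core in seconds to a
few minutes.

## Known limitations

* Single whisking frequency; real whisking occupies a band, and touch or
  texture signals are not modelled.
* No recurrent layer-4 circuitry; downstream phases are i.i.d. across
  neurons by construction, so temporal and population distributions
  coincide exactly rather than approximately.
* The downstream neuron is linear-Poisson: no refractoriness,
  conductances, or spike-history effects.
* No noise term is added to the mean-field flow; the pinning observed at
  small N (roughly N ≲ 70, initial-condition dependent) would be
  softened by the spike noise the deterministic limit discards.
* Single-component von Mises fits are reported (and flagged) even in
  bimodal regimes; no mixture fitting.
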