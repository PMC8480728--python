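# whiskstdp

Rodents sweep their whiskers rhythmically, and "whisking neurons" along the
somatosensory pathway fire preferentially at a particular phase of that
cycle.  Preferred phases in the ventral posteromedial thalamus (VPM) are
narrowly distributed, so naively pooling ~100 VPM inputs should produce an
even narrower distribution in the downstream layer-4 inhibitory (L4I)
barrel-cortex population — yet the observed L4I distribution is wide, and
its mean sits far from the delayed thalamic mean.  `whiskstdp` implements a
model in which spike-timing-dependent plasticity (STDP) at the
thalamocortical synapses resolves this: the synaptic weight profile never
settles, the downstream preferred phase drifts around the whisking cycle
with phase-dependent velocity, and the fraction of time spent at each phase
defines a stationary circular distribution shaped by the learning rule
rather than by the input statistics alone.

This package is for computational neuroscientists who want to simulate,
analyse, or extend that mechanism.

## Model

N thalamic neurons fire as independent inhomogeneous Poisson processes,

&emsp; ⟨ρ_k(t)⟩ = D (1 + γ cos(νt − φ_k)),

with preferred phases φ_k distributed as von Mises(κ_VPM, ψ_VPM).  A single
downstream linear-Poisson neuron fires at rate (1/N) Σ_k w_k ρ_k(t − d).
Its tuning is set by the circular order parameters of the weight profile,
w̄ and w̃e^{iψ} (mean and first circular Fourier component): mean rate
D·w̄, modulation depth γ·w̃/w̄, preferred phase ψ_L4I = ψ + νd.

Each pre/post spike pair updates its synapse by

&emsp; Δw = λ [ f₊(w) K₊(Δt) − f₋(w) K₋(Δt) ],&emsp; Δt = t_post − t_pre,

with weight dependence f₊ = (1−w)^μ, f₋ = α w^μ and unit-area temporal
kernels K±, either temporally asymmetric (one-sided exponentials, τ± time
constants) or symmetric (Gaussians).  In the slow-learning limit the weights
follow a deterministic mean-field flow driven by the spike-train
cross-correlations; the rhythmic part enters only through the kernel
Fourier components K̃± e^{iΩ±} at the whisking frequency.  The package
provides:

* `rhythmic_model` — population, tuning, order parameters, phase placement;
* `stdp_rules` — f±, kernels, kernel Fourier transforms;
* `meanfield_dynamics` — drift terms and Euler integration of the flow;
* `fixed_point_solver` — self-consistent stationary profiles
  w*(φ) = (1 + α^{1/μ} ((1+X₋)/(1+X₊))^{1/μ})^{-1};
* `spiking_simulator` — an event-level Poisson/STDP simulation used to
  validate the mean field;
* `phase_analysis` — drift velocity, time-weighted phase occupancy, von
  Mises fits (κ_L4I, ψ_L4I, γ_L4I);
* `pooling_baseline` — the plasticity-free quenched-pooling null model;
* `cli` — configs, figure-style presets, and parameter sweeps.

## Worked example

```python
import numpy as np
from whiskstdp import *

spec  = VonMisesSpec(kappa=1.0, psi=5 * np.pi / 6)
model = make_thalamic_model(N=150, D=10.0, gamma=1.0,
                            nu=hz_to_angular(7.0), d=0.003, phase_spec=spec)
rule  = STDPRule("asymmetric_exponential", tau_plus=0.022, tau_minus=0.050,
                 mu=0.01, alpha=1.1, lam=0.01)

traj = euler_integrate(default_initial_weights(150, seed=0), rule, model,
                       n_steps=200_000, dt=0.1, record_every=10)
times, psi = phase_trajectory(traj, model)
dist = temporal_phase_distribution(psi, times, fit_mode="nls")
print(f"kappa_L4I = {dist.fit.kappa:.2f}, psi_L4I = {dist.fit.psi:.2f} rad")
```

```
kappa_L4I = 1.15, psi_L4I = 0.87 rad
```

The weights never converge: the order parameters trace a limit cycle and
the downstream preferred phase circles the whisking cycle roughly 250 times
in this run.  The fitted concentration says the induced L4I phase
distribution is about as wide as the thalamic one (κ ≈ 1), and its mean
(≈0.8 rad) is set by the STDP rule — more than 2 rad away from the delayed
thalamic mean ψ_VPM + νd ≈ 2.75 rad, which is what the plasticity-free
pooling baseline would predict:

```python
ens = quenched_ensemble(spec, N=100, reps=10_000, mode="random", seed=0,
                        nu=model.nu, d=model.d)
print(f"baseline: kappa = {ens.fit.kappa:.1f}, psi = {ens.fit.psi:.2f} rad")
```

```
baseline: kappa = 32.9, psi = 2.75 rad
```

The same experiment from a shell:

```
whiskstdp preset fig3 --out out_fig3
whiskstdp sweep --param rule.mu --grid 0.01,0.06,0.07,0.1 --out out_mu
```

Each run directory contains the echoed `config.json`, a `trajectory.csv`
with columns `time, w_bar, w_tilde, psi` (rescaled time s = λt; `psi`
blank where the first Fourier component vanishes), a
`phase_histogram.csv` with `bin_center_rad, density`, and a
`summary.json` with the fitted `kappa_L4I`, `psi_L4I_rad`,
`gamma_L4I_mean` and run diagnostics.

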