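"""Deterministic mean-field dynamics of the synaptic weight profile.

In the slow-learning limit the stochastic pairwise STDP updates average out
and each weight follows the deterministic flow

    dw_j / ds = F_d_j + w_bar * F0_j + w_tilde * F1_j,

in rescaled time ``s = lam * t``, where the three drift terms capture the
pre/post spike correlations of the rhythmically driven feed-forward circuit:

* ``F_d`` — the O(1/N) self-contribution of synapse ``j`` through the delta
  peak of its own pre/post correlation at the transmission delay ``d``;
* ``F0`` — the phase-independent (mean-rate) competition between
  potentiation and depression, entering through the kernel areas;
* ``F1`` — the rhythmic term, entering through the kernel Fourier
  components at the whisking frequency and the phase of each synapse
  relative to the downstream preferred phase.

The flow is integrated with the explicit Euler method (weights clamped to
[0, 1] after every step).  All distribution-level results are invariant to
the overall time scale: multiplying the learning rate by ``c`` while
dividing the step by ``c`` reproduces the identical trajectory per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rhythmic_model import (
    OrderParameters,
    ThalamicModel,
    WeightProfile,
    order_parameters,
)
from .stdp_rules import STDPRule, f_minus, f_plus, kernel_fourier, kernel_value

__all__ = [
    "DriftTerms",
    "Trajectory",
    "cross_corr_pre_pre",
    "cross_corr_pre_post",
    "drift_terms",
    "meanfield_rhs",
    "euler_integrate",
]


@dataclass(frozen=True)
class DriftTerms:
    """Per-synapse drift contributions; ``F_d`` carries the 1/N prefactor."""

    F_d: np.ndarray
    F_0: np.ndarray
    F_1: np.ndarray


@dataclass
class Trajectory:
    """Recorded order-parameter series (and optional snapshots) of a run.

    ``times`` are rescaled (s = lam * t) and strictly increasing; ``psi`` is
    valid only where ``psi_defined`` is True.  ``weights_final`` is the
    state at the last integration step; ``snapshots`` (n_records x N) is
    kept only when requested.
    """

    times: np.ndarray
    w_bar: np.ndarray
    w_tilde: np.ndarray
    psi: np.ndarray
    psi_defined: np.ndarray
    weights_final: np.ndarray
    snapshots: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "w_bar": self.w_bar,
                "w_tilde": self.w_tilde,
                "psi": np.where(self.psi_defined, self.psi, np.nan),
            }
        )

    def write_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def cross_corr_pre_pre(model: ThalamicModel, j: int, k: int, dt):
    """Correlation of thalamic spike trains ``j`` and ``k`` at lag ``dt``.

    Returns ``(smooth, delta_weight)``: the smooth part
    ``D**2 * (1 + (gamma**2/2) * cos(nu*dt + phi_j - phi_k))`` and the
    weight of the Poisson self-correlation atom at dt = 0 (``D`` when
    j == k, else 0), kept separate from the smooth density.
    """
    if not (1 <= j <= model.N and 1 <= k <= model.N):
        raise IndexError("neuron index out of range")
    dt = np.asarray(dt, dtype=float)
    phi_j, phi_k = model.phases[j - 1], model.phases[k - 1]
    smooth = model.D**2 * (
        1.0 + 0.5 * model.gamma**2 * np.cos(model.nu * dt + phi_j - phi_k)
    )
    delta_weight = model.D if j == k else 0.0
    return smooth, delta_weight


def cross_corr_pre_post(
    j: int,
    profile: WeightProfile,
    op: OrderParameters,
    model: ThalamicModel,
    dt,
):
    """Correlation of pre-synaptic neuron ``j`` with the pooled post neuron.

    Returns ``(smooth, delta_weight_at_d)``: the smooth part
    ``D**2 * (w_bar + (gamma**2/2) * w_tilde * cos(nu*(dt-d) + phi_j - psi))``
    plus the atom of weight ``w_j * D / N`` sitting at the delay ``dt = d``
    (the downstream echo of neuron j's own spikes).
    """
    if not 1 <= j <= model.N:
        raise IndexError("neuron index out of range")
    dt = np.asarray(dt, dtype=float)
    phi_j = model.phases[j - 1]
    psi = op.psi if op.psi_defined else 0.0
    smooth = model.D**2 * (
        op.w_bar
        + 0.5 * model.gamma**2
        * op.w_tilde
        * np.cos(model.nu * (dt - model.d) + phi_j - psi)
    )
    delta_weight_at_d = profile.weights[j - 1] * model.D / model.N
    return smooth, delta_weight_at_d


def drift_terms(
    profile: WeightProfile,
    phases: np.ndarray,
    op: OrderParameters,
    rule: STDPRule,
    model: ThalamicModel,
) -> DriftTerms:
    """Evaluate the three drift contributions at the current weight state.

    When the first Fourier component vanishes (``psi`` undefined) the
    rhythmic term is multiplied by ``w_tilde = 0`` in the flow, so any
    placeholder phase is immaterial; 0 is used.
    """
    w = profile.weights
    phases = np.asarray(phases, dtype=float)
    fp = f_plus(w, rule.mu)
    fm = f_minus(w, rule.mu, rule.alpha)
    kf = kernel_fourier(rule, model.nu)

    k_plus_d = float(kernel_value(rule, "+", model.d))
    k_minus_d = float(kernel_value(rule, "-", model.d))
    F_d = w * (model.D / model.N) * (fp * k_plus_d - fm * k_minus_d)

    F_0 = model.D**2 * (kf.k_bar_plus * fp - kf.k_bar_minus * fm)

    psi = op.psi if op.psi_defined else 0.0
    shift = model.nu * model.d + psi
    F_1 = (
        model.D**2
        * 0.5
        * model.gamma**2
        * (
            kf.k_tilde_plus * fp * np.cos(phases - kf.omega_plus - shift)
            - kf.k_tilde_minus * fm * np.cos(phases - kf.omega_minus - shift)
        )
    )
    return DriftTerms(F_d=F_d, F_0=F_0, F_1=F_1)


def meanfield_rhs(
    state: WeightProfile,
    phases: np.ndarray,
    rule: STDPRule,
    model: ThalamicModel,
    include_self_term: bool = True,
) -> np.ndarray:
    """Weight velocity ``F_d + w_bar*F0 + w_tilde*F1`` in rescaled time.

    ``include_self_term=False`` drops the O(1/N) delta-atom contribution,
    realising the strict continuum limit.
    """
    op = order_parameters(state, phases)
    terms = drift_terms(state, phases, op, rule, model)
    rhs = op.w_bar * terms.F_0 + op.w_tilde * terms.F_1
    if include_self_term:
        rhs = rhs + terms.F_d
    return rhs


def euler_integrate(
    init: WeightProfile,
    rule: STDPRule,
    model: ThalamicModel,
    n_steps: int,
    dt: float = 0.1,
    record_every: int = 10,
    include_self_term: bool = True,
    record_snapshots: bool = False,
) -> Trajectory:
    """Explicit Euler integration of the mean-field flow.

    Each step advances ``w += lam * dt * rhs`` and clamps to [0, 1]; the
    recorded times are rescaled, ``s = lam * dt * step``.  The trajectory
    is deterministic given the initial profile.  A non-finite weight aborts
    with the offending step index.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    phases = model.phases
    w = init.weights.copy()
    if w.size != model.N:
        raise ValueError("initial profile length must match model.N")
    ds = rule.lam * dt

    kf = kernel_fourier(rule, model.nu)
    k_plus_d = float(kernel_value(rule, "+", model.d))
    k_minus_d = float(kernel_value(rule, "-", model.d))
    shift0 = model.nu * model.d
    D2 = model.D**2
    half_g2 = 0.5 * model.gamma**2

    n_rec = n_steps // record_every
    times = np.empty(n_rec)
    w_bar = np.empty(n_rec)
    w_tilde = np.empty(n_rec)
    psi = np.empty(n_rec)
    psi_ok = np.empty(n_rec, dtype=bool)
    snaps = np.empty((n_rec, w.size)) if record_snapshots else None

    exp_iphi = np.exp(1j * phases)
    rec = 0
    mu, alpha = rule.mu, rule.alpha
    for step in range(1, n_steps + 1):
        # inlined meanfield_rhs (hot loop; same arithmetic, no object churn)
        fp = np.ones_like(w) if mu == 0.0 else (1.0 - w) ** mu
        fm = np.full_like(w, alpha) if mu == 0.0 else alpha * w**mu
        z = np.mean(w * exp_iphi)
        wb = w.mean()
        wt = abs(z)
        psi_now = np.angle(z) if wt >= 1e-12 else 0.0
        shift = shift0 + psi_now
        rhs = wb * D2 * (fp - fm) + wt * D2 * half_g2 * (
            kf.k_tilde_plus * fp * np.cos(phases - kf.omega_plus - shift)
            - kf.k_tilde_minus * fm * np.cos(phases - kf.omega_minus - shift)
        )
        if include_self_term:
            rhs += w * (model.D / model.N) * (fp * k_plus_d - fm * k_minus_d)
        w = w + ds * rhs
        if not np.all(np.isfinite(w)):
            raise FloatingPointError(f"non-finite weight at step {step}")
        np.clip(w, 0.0, 1.0, out=w)
        if step % record_every == 0:
            times[rec] = step * ds
            w_bar[rec] = w.mean()
            z = np.mean(w * exp_iphi)
            w_tilde[rec] = abs(z)
            psi_ok[rec] = w_tilde[rec] >= 1e-12
            psi[rec] = np.angle(z) if psi_ok[rec] else 0.0
            if snaps is not None:
                snaps[rec] = w
            rec += 1

    return Trajectory(
        times=times[:rec],
        w_bar=w_bar[:rec],
        w_tilde=w_tilde[:rec],
        psi=psi[:rec],
        psi_defined=psi_ok[:rec],
        weights_final=w,
        snapshots=None if snaps is None else snaps[:rec],
    )


def default_initial_weights(N: int, seed: int = 0) -> WeightProfile:
    """I.i.d. uniform(0.3, 0.7) initial weights with a recorded seed.

    Limit-cycle statistics are initialisation-independent after the
    transient; the interior start keeps early dynamics away from the
    clamping boundaries.
    """
    rng = np.random.default_rng(seed)
    return WeightProfile(rng.uniform(0.3, 0.7, size=N))
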