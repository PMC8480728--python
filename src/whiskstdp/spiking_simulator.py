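"""Event-level spiking simulation: the stochastic oracle for the mean field.

Thalamic neurons fire as independent inhomogeneous Poisson processes with
the rhythmic rate of the upstream model (generated by thinning against the
bound ``D*(1+gamma)``).  The downstream neuron is a linear Poisson unit:
each thalamic spike of neuron ``k`` at time ``t`` elicits a downstream
spike at ``t + d`` with probability ``w_k / N`` — a thinning realisation of
the pooled rate.  Every pre/post spike pair within a truncation window
contributes additively to the weight update through the pairwise STDP rule.

Weights are held frozen over batches of many whisking cycles and updated in
bulk at batch boundaries; in the slow-learning regime (lam << 1) this is
equivalent to strictly online updating to first order in the learning rate,
and it is the regime in which the deterministic mean-field flow is derived.
Agreement of the order-parameter trajectories between this simulator and
the Euler-integrated mean field validates both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meanfield_dynamics import Trajectory
from .rhythmic_model import (
    ThalamicModel,
    WeightProfile,
    order_parameters,
)
from .stdp_rules import STDPRule, f_minus, f_plus, kernel_value

__all__ = [
    "SpikeTrain",
    "generate_thalamic_spikes",
    "downstream_spikes",
    "apply_stdp_window",
    "run_spiking_simulation",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (s) of one neuron."""

    neuron_id: int
    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self):
        return self.times.size


def generate_thalamic_spikes(
    model: ThalamicModel, T: float, seed: int, t0: float = 0.0
) -> list[SpikeTrain]:
    """Inhomogeneous Poisson trains on [t0, t0+T) for every thalamic neuron.

    Thinning: candidate spikes at the constant bound rate ``D*(1+gamma)``
    are kept with probability rate(t)/bound.  Trains are independent across
    neurons and reproducible given the seed.
    """
    if T <= 0:
        raise ValueError("duration T must be positive")
    rng = np.random.default_rng(seed)
    bound = model.D * (1.0 + model.gamma)
    trains = []
    for k in range(model.N):
        n_cand = rng.poisson(bound * T)
        cand = np.sort(rng.uniform(t0, t0 + T, size=n_cand))
        rate = model.D * (
            1.0 + model.gamma * np.cos(model.nu * cand - model.phases[k])
        )
        keep = rng.uniform(0.0, bound, size=n_cand) < rate
        times = cand[keep]
        if times.size > 1 and np.any(np.diff(times) <= 0):
            # duplicate uniforms are measure-zero; dedupe only if they occur
            times = np.unique(times)
        trains.append(SpikeTrain(neuron_id=k + 1, times=times))
    return trains


def downstream_spikes(
    trains: list[SpikeTrain],
    weights: WeightProfile,
    model: ThalamicModel,
    seed: int,
) -> SpikeTrain:
    """Linear-Poisson downstream train: thin each input spike by w_k/N.

    A thalamic spike at ``t`` from neuron ``k`` produces a downstream spike
    at ``t + d`` with probability ``w_k / N``; weights are assumed constant
    over the window.
    """
    rng = np.random.default_rng(seed)
    w = weights.weights
    if len(trains) != w.size:
        raise ValueError("one train per synapse required")
    out = []
    for k, train in enumerate(trains):
        p = w[k] / model.N
        keep = rng.uniform(0.0, 1.0, size=len(train)) < p
        out.append(train.times[keep] + model.d)
    times = np.unique(np.concatenate(out)) if out else np.empty(0)
    return SpikeTrain(neuron_id=0, times=times)


def apply_stdp_window(
    pre_trains: list[SpikeTrain],
    post_train: SpikeTrain,
    rule: STDPRule,
    weights: WeightProfile,
    window: float | None = None,
) -> WeightProfile:
    """Batch-apply pairwise STDP updates for all pre/post pairs.

    Pair lags beyond ``window`` (default ``10 * max(tau_plus, tau_minus)``,
    beyond which the kernel mass is negligible) are truncated.  All pair
    contributions are evaluated at the pre-update weights and accumulated
    additively before a single clamped application — processing order is
    immaterial by construction.
    """
    tau_max = max(rule.tau_plus, rule.tau_minus)
    if window is None:
        window = 10.0 * tau_max
    if window < 10.0 * tau_max:
        raise ValueError("window must be at least 10 * max(tau_plus, tau_minus)")
    w = weights.weights.copy()
    post = post_train.times
    if post.size == 0:
        return WeightProfile(w)
    fp = f_plus(w, rule.mu)
    fm = f_minus(w, rule.mu, rule.alpha)
    delta = np.zeros_like(w)
    gaussian = rule.family == "symmetric_gaussian"
    tp, tm = rule.tau_plus, rule.tau_minus
    norm_p = 1.0 / (tp * np.sqrt(2.0 * np.pi))
    norm_m = 1.0 / (tm * np.sqrt(2.0 * np.pi))
    for k, train in enumerate(pre_trains):
        pre = train.times
        if pre.size == 0:
            continue
        lo = np.searchsorted(post, pre - window, side="left")
        hi = np.searchsorted(post, pre + window, side="right")
        n_pairs = hi - lo
        total = int(n_pairs.sum())
        if total == 0:
            continue
        # flat array of all post-minus-pre lags within the window
        idx = np.repeat(np.arange(pre.size), n_pairs)
        within = np.arange(total) - np.repeat(np.cumsum(n_pairs) - n_pairs, n_pairs)
        offsets = within + np.repeat(lo, n_pairs)
        dt = post[offsets] - pre[idx]
        # inlined kernel_value for both branches (hot loop)
        if gaussian:
            kp_sum = norm_p * np.exp(-0.5 * (dt / tp) ** 2).sum()
            km_sum = norm_m * np.exp(-0.5 * (dt / tm) ** 2).sum()
        else:
            pos = dt[dt > 0]
            neg = dt[dt < 0]
            kp_sum = np.exp(-pos / tp).sum() / tp
            km_sum = np.exp(neg / tm).sum() / tm
        delta[k] = rule.lam * (fp[k] * kp_sum - fm[k] * km_sum)
    return WeightProfile(np.clip(w + delta, 0.0, 1.0))


def run_spiking_simulation(
    model: ThalamicModel,
    rule: STDPRule,
    init: WeightProfile,
    T: float,
    update_interval: float | None = None,
    seed: int = 0,
) -> Trajectory:
    """Alternate spike generation (weights frozen) with batch STDP updates.

    ``update_interval`` defaults to 50 whisking cycles, far longer than the
    whisking period as the batching approximation requires.  Order
    parameters are recorded once per batch at rescaled times
    ``s = lam * t``; spikes in a margin of one truncation window around
    each batch edge pair only within their own batch (an O(window/batch)
    edge effect, negligible for the default sizes).
    """
    if update_interval is None:
        update_interval = 50.0 * 2.0 * np.pi / model.nu
    period = 2.0 * np.pi / model.nu
    if update_interval < 5.0 * period:
        raise ValueError("update_interval must span many whisking cycles")
    n_windows = int(np.ceil(T / update_interval))
    rng = np.random.default_rng(seed)

    w = WeightProfile(init.weights.copy())
    times = np.empty(n_windows)
    w_bar = np.empty(n_windows)
    w_tilde = np.empty(n_windows)
    psi = np.empty(n_windows)
    psi_ok = np.empty(n_windows, dtype=bool)

    t0 = 0.0
    for i in range(n_windows):
        span = min(update_interval, T - t0)
        if span <= 1e-12:  # float roundoff on the last window
            n_windows = i
            break
        pre = generate_thalamic_spikes(
            model, span, seed=int(rng.integers(2**31 - 1)), t0=t0
        )
        post = downstream_spikes(pre, w, model, seed=int(rng.integers(2**31 - 1)))
        w = apply_stdp_window(pre, post, rule, w)
        op = order_parameters(w, model.phases)
        times[i] = rule.lam * (t0 + span)
        w_bar[i] = op.w_bar
        w_tilde[i] = op.w_tilde
        psi[i] = op.psi
        psi_ok[i] = op.psi_defined
        t0 += span

    return Trajectory(
        times=times[:n_windows],
        w_bar=w_bar[:n_windows],
        w_tilde=w_tilde[:n_windows],
        psi=psi[:n_windows],
        psi_defined=psi_ok[:n_windows],
        weights_final=w.weights.copy(),
    )


def spike_trains_to_frame(trains: list[SpikeTrain]):
    """Two-column (neuron_id, time_s) DataFrame for writing/inspection."""
    import pandas as pd

    ids = np.concatenate([np.full(len(t), t.neuron_id) for t in trains])
    ts = np.concatenate([t.times for t in trains])
    return pd.DataFrame({"neuron_id": ids.astype(int), "time_s": ts})
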