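"""Rhythmic upstream population and downstream linear-Poisson tuning.

A population of ``N`` thalamic (VPM) whisking neurons fires as independent
inhomogeneous Poisson processes whose rates follow the whisking cycle,

    rate_k(t) = D * (1 + gamma * cos(nu*t - phi_k)),

where ``phi_k`` is the preferred phase of neuron ``k``.  Preferred phases are
distributed over the circle according to a von Mises density with
concentration ``kappa`` and mean direction ``psi``.  The downstream layer-4
inhibitory (L4I) neuron pools these inputs linearly with synaptic weights
``w_k`` in [0, 1] and a transmission delay ``d``; its tuning is fully
determined by the circular order parameters of the weight profile:
the mean weight ``w_bar`` and the first circular Fourier component
``w_tilde * exp(i*psi)``.

All angles are in radians and canonically wrapped to ``[-pi, pi)``;
:func:`wrap_angle` is the single wrapping utility shared across the package.
Rates are in spikes/s, times in seconds, and ``nu`` is an angular frequency
in rad/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "wrap_angle",
    "VonMisesSpec",
    "ThalamicModel",
    "WeightProfile",
    "OrderParameters",
    "DownstreamTuning",
    "von_mises_density",
    "von_mises_cdf",
    "thalamic_rate",
    "place_phases_quantile",
    "sample_phases_accept_reject",
    "order_parameters",
    "downstream_tuning",
]

#: magnitudes of the first Fourier component below this are treated as zero,
#: in which case the associated phase is undefined (never NaN arithmetic).
W_TILDE_TOL = 1e-12


def wrap_angle(phi):
    """Wrap angle(s) to the canonical range ``[-pi, pi)``.

    Accepts scalars or arrays; the shared wrapping convention for the whole
    package.
    """
    return np.mod(np.asarray(phi) + np.pi, 2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class VonMisesSpec:
    """Concentration and mean direction of a circular (von Mises) density.

    ``kappa = 0`` is the uniform density ``1/(2*pi)``; large ``kappa``
    concentrates the mass around ``psi``.
    """

    kappa: float
    psi: float = 0.0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError(f"kappa must be non-negative, got {self.kappa}")
        object.__setattr__(self, "psi", float(wrap_angle(self.psi)))


@dataclass(frozen=True)
class ThalamicModel:
    """Upstream rhythmic population: size, rate parameters, delay, phases.

    Parameters
    ----------
    N : number of thalamic neurons (>= 1).
    D : mean firing rate over one whisking cycle, spikes/s.
    gamma : modulation depth in [0, 1] (rate stays non-negative).
    nu : angular whisking frequency, rad/s.
    d : thalamocortical transmission delay, s.
    phases : length-N preferred phases, wrapped to [-pi, pi).
    """

    N: int
    D: float
    gamma: float
    nu: float
    d: float
    phases: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.d < 0:
            raise ValueError("delay d must be non-negative")
        phases = wrap_angle(np.asarray(self.phases, dtype=float))
        if phases.shape != (self.N,):
            raise ValueError(f"phases must have shape ({self.N},)")
        object.__setattr__(self, "phases", phases)


@dataclass(frozen=True)
class WeightProfile:
    """Synaptic weights in [0, 1], index-aligned with the thalamic phases."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1-D array")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)

    def __len__(self):
        return self.weights.size


@dataclass(frozen=True)
class OrderParameters:
    """Mean weight and first circular Fourier component of a weight profile.

    ``w_tilde * exp(i*psi)`` is the (non-negative magnitude, argument) polar
    form of the first component; when ``w_tilde`` vanishes the argument is
    undefined and ``psi_defined`` is False (``psi`` then holds 0.0 as a
    placeholder, never to be consumed).
    """

    w_bar: float
    w_tilde: float
    psi: float
    psi_defined: bool = True


@dataclass(frozen=True)
class DownstreamTuning:
    """Rhythmic tuning of the downstream pooled (L4I) neuron."""

    D_L4I: float
    gamma_L4I: float
    psi_L4I: float
    psi_defined: bool = True


def von_mises_density(spec: VonMisesSpec, phi):
    """Von Mises probability density at angle(s) ``phi``.

    ``exp(kappa*cos(phi - psi)) / (2*pi*I0(kappa))``; 2*pi-periodic in phi
    and normalised over one circle.
    """
    phi = np.asarray(phi, dtype=float)
    # i0e avoids overflow at large concentration
    return np.exp(spec.kappa * (np.cos(phi - spec.psi) - 1.0)) / (
        2.0 * np.pi * special.i0e(spec.kappa)
    )


def von_mises_cdf(spec: VonMisesSpec, phi):
    """CDF of the von Mises density on [-pi, pi), measured from -pi."""
    from scipy.stats import vonmises

    phi = np.asarray(phi, dtype=float)
    if spec.kappa == 0:
        return (phi + np.pi) / (2.0 * np.pi)
    dist = vonmises(kappa=spec.kappa, loc=spec.psi)
    return dist.cdf(phi) - dist.cdf(-np.pi)


def thalamic_rate(model: ThalamicModel, k: int, t):
    """Instantaneous rate of neuron ``k`` (1-based index) at time(s) ``t``.

    ``D * (1 + gamma*cos(nu*t - phi_k))``, non-negative for gamma <= 1.
    """
    if not 1 <= k <= model.N:
        raise IndexError(f"neuron index {k} out of range 1..{model.N}")
    t = np.asarray(t, dtype=float)
    return model.D * (1.0 + model.gamma * np.cos(model.nu * t - model.phases[k - 1]))


def place_phases_quantile(spec: VonMisesSpec, N: int) -> np.ndarray:
    """Deterministic phase placement at the k/N quantiles of the density.

    phi_k solves ``CDF(phi_k) = k/N`` for k = 1..N with the CDF measured from
    -pi; the k = N phase (quantile 1) is the upper circle boundary, wrapped
    to -pi.  Phases are returned sorted ascending in [-pi, pi).  No
    randomness is involved; this realises the phase distribution without
    quenched disorder.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    targets = np.arange(1, N + 1) / N
    if spec.kappa == 0:
        phases = -np.pi + 2.0 * np.pi * targets
    else:
        from scipy.optimize import brentq

        phases = np.empty(N)
        for i, q in enumerate(targets):
            if q >= 1.0:
                phases[i] = np.pi
            else:
                phases[i] = brentq(
                    lambda x, q=q: von_mises_cdf(spec, x) - q,
                    -np.pi,
                    np.pi,
                    xtol=1e-10,
                )
    return np.sort(wrap_angle(phases))


def sample_phases_accept_reject(spec: VonMisesSpec, N: int, seed: int) -> np.ndarray:
    """I.i.d. von Mises phases by accept-reject against a uniform proposal.

    Proposals are uniform on [-pi, pi) and accepted with probability
    ``exp(kappa*(cos(phi - psi) - 1))`` (envelope constant
    ``exp(kappa)/(2*pi*I0(kappa))``).  Reproducible given ``seed``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(N)
    filled = 0
    while filled < N:
        m = max(2 * (N - filled), 16)
        proposal = rng.uniform(-np.pi, np.pi, size=m)
        u = rng.uniform(0.0, 1.0, size=m)
        accept = u <= np.exp(spec.kappa * (np.cos(proposal - spec.psi) - 1.0))
        take = proposal[accept][: N - filled]
        out[filled : filled + take.size] = take
        filled += take.size
    return wrap_angle(out)


def order_parameters(profile: WeightProfile, phases: np.ndarray) -> OrderParameters:
    """Discrete circular order parameters of a weight profile.

    ``w_bar = mean(w)`` and ``w_tilde * exp(i*psi) = mean(w * exp(i*phi))``
    with ``w_tilde`` returned as a non-negative magnitude.  When the first
    component is numerically zero the phase is flagged undefined.
    """
    w = profile.weights
    phases = np.asarray(phases, dtype=float)
    if w.size != phases.size:
        raise ValueError("weights and phases must have equal length")
    if w.size == 0:
        raise ValueError("empty profile")
    w_bar = float(np.mean(w))
    z = np.mean(w * np.exp(1j * phases))
    w_tilde = float(abs(z))
    if w_tilde < W_TILDE_TOL:
        return OrderParameters(w_bar, 0.0, 0.0, psi_defined=False)
    return OrderParameters(w_bar, w_tilde, float(wrap_angle(np.angle(z))), True)


def downstream_tuning(op: OrderParameters, model: ThalamicModel) -> DownstreamTuning:
    """Tuning of the pooled downstream neuron from the order parameters.

    Mean rate ``D*w_bar``, modulation depth ``gamma*w_tilde/w_bar`` (zero by
    convention when ``w_bar = 0``), preferred phase ``psi + nu*d`` wrapped.
    """
    if op.w_bar < 0:
        raise ValueError("w_bar must be non-negative")
    if op.w_bar == 0 and op.w_tilde > 0:
        raise ValueError("invariant violation: w_tilde > 0 with w_bar = 0")
    D_L4I = model.D * op.w_bar
    gamma_L4I = 0.0 if op.w_bar == 0 else model.gamma * op.w_tilde / op.w_bar
    if not op.psi_defined:
        return DownstreamTuning(D_L4I, gamma_L4I, 0.0, psi_defined=False)
    psi_L4I = float(wrap_angle(op.psi + model.nu * model.d))
    return DownstreamTuning(D_L4I, gamma_L4I, psi_L4I, True)


def make_thalamic_model(
    N: int,
    D: float,
    gamma: float,
    nu: float,
    d: float,
    phase_spec: VonMisesSpec,
    phase_mode: str = "quantile",
    seed: int | None = None,
) -> ThalamicModel:
    """Convenience constructor: build the population with generated phases.

    ``phase_mode`` is ``"quantile"`` (deterministic placement, the default —
    no quenched disorder) or ``"sample"`` (i.i.d. accept-reject draws,
    requires ``seed``).
    """
    if phase_mode == "quantile":
        phases = place_phases_quantile(phase_spec, N)
    elif phase_mode == "sample":
        if seed is None:
            raise ValueError("phase_mode='sample' requires a seed")
        phases = sample_phases_accept_reject(phase_spec, N, seed)
    else:
        raise ValueError(f"unknown phase_mode {phase_mode!r}")
    return ThalamicModel(N=N, D=D, gamma=gamma, nu=nu, d=d, phases=phases)


def hz_to_angular(freq_hz: float) -> float:
    """Convert an ordinary frequency in Hz to angular frequency in rad/s."""
    return 2.0 * math.pi * freq_hz
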