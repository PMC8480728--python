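"""Plasticity-free pooling baseline: quenched disorder without learning.

If the thalamocortical weights are unstructured (all equal, or random but
activity-independent), the downstream preferred phase is simply the
argument of the weighted resultant of the pooled upstream phases, shifted
by the transmission delay.  Repeatedly drawing the upstream phases (and, in
random mode, the weights) gives the quenched-disorder ensemble of
downstream phases.  Its concentration grows with the number of pooled
neurons — pooling averages the phase dispersion away — and its mean stays
locked to the upstream mean phase plus the delay lag.  This is the null
model the plastic dynamics are contrasted with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phase_analysis import fit_von_mises
from .rhythmic_model import VonMisesSpec, sample_phases_accept_reject, wrap_angle

__all__ = ["PoolingEnsemble", "pooled_phase", "quenched_ensemble"]

MODES = ("uniform", "random")


@dataclass(frozen=True)
class PoolingEnsemble:
    """Quenched ensemble of downstream preferred phases and its fit."""

    mode: str
    N: int
    reps: int
    seed: int
    phases: np.ndarray
    fit: VonMisesSpec

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"phase_rad": self.phases})

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "N": self.N,
            "reps": self.reps,
            "kappa_L4I": self.fit.kappa,
            "psi_L4I": self.fit.psi,
        }


def pooled_phase(phases: np.ndarray, weights: np.ndarray, nu: float, d: float):
    """Preferred phase of a neuron pooling rhythmic inputs with fixed weights.

    The summed rate of cosine-tuned inputs is itself cosine-tuned with
    phase ``arg(sum_k w_k exp(i*phi_k))``; the delay adds a lag ``nu*d``.
    Returns ``(phase, defined)``; a vanishing resultant leaves the phase
    undefined.
    """
    phases = np.asarray(phases, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if phases.size != weights.size or phases.size == 0:
        raise ValueError("phases and weights must be non-empty and aligned")
    if np.any(weights < 0) or not np.any(weights > 0):
        raise ValueError("weights must be non-negative and not all zero")
    z = np.sum(weights * np.exp(1j * phases))
    if abs(z) < 1e-12 * weights.sum():
        return 0.0, False
    return float(wrap_angle(np.angle(z) + nu * d)), True


def quenched_ensemble(
    spec: VonMisesSpec,
    N: int,
    reps: int,
    mode: str = "uniform",
    seed: int = 0,
    nu: float = 0.0,
    d: float = 0.0,
) -> PoolingEnsemble:
    """Ensemble of pooled phases over repeated draws of the upstream phases.

    Per repetition, N phases are drawn i.i.d. from the upstream von Mises
    density; ``mode="uniform"`` pools them with equal weights, while
    ``mode="random"`` draws i.i.d. uniform(0, 1) weights as well.  The
    ensemble of downstream phases is then fitted with a von Mises
    distribution.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if reps < 100:
        raise ValueError("need reps >= 100 for a meaningful fit")
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    ok = np.zeros(reps, dtype=bool)
    for r in range(reps):
        phases = sample_phases_accept_reject(
            spec, N, seed=int(rng.integers(2**31 - 1))
        )
        if mode == "random":
            weights = rng.uniform(0.0, 1.0, size=N)
            if not np.any(weights > 0):  # pragma: no cover
                weights = np.ones(N)
        else:
            weights = np.ones(N)
        out[r], ok[r] = pooled_phase(phases, weights, nu, d)
    phases_out = out[ok]
    fit = fit_von_mises(phases_out)
    return PoolingEnsemble(
        mode=mode, N=N, reps=reps, seed=seed, phases=phases_out, fit=fit
    )
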