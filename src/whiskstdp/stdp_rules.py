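"""STDP rule: weight dependence, temporal kernels, and kernel Fourier data.

A pre/post spike pair with lag ``dt = t_post - t_pre`` changes the synaptic
weight by

    dw = lam * ( f_plus(w) * K_plus(dt) - f_minus(w) * K_minus(dt) ),

where the weight-dependence factors ``f_plus(w) = (1-w)**mu`` and
``f_minus(w) = alpha * w**mu`` softly bound the weight to [0, 1] (mu = 0 is
the additive rule, mu = 1 the fully multiplicative one) and the temporal
kernels are normalised to unit area.  Two kernel families are supported:

* ``asymmetric_exponential`` — causal potentiation / anti-causal depression,
  ``K_pm(dt) = exp(-|dt|/tau_pm)/tau_pm`` on the corresponding half-line;
* ``symmetric_gaussian`` — zero-mean Gaussians of width ``tau_pm``; only the
  absolute lag matters.

The mean-field dynamics only see the kernels through their zeroth moment
(1 for both families) and their Fourier transform at the whisking frequency,
``K_tilde_pm * exp(i*Omega_pm) = \\int K_pm(u) exp(-i*nu*u) du``, computed
here in closed form and cached per (rule, nu).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .rhythmic_model import wrap_angle

__all__ = [
    "STDPRule",
    "KernelFourier",
    "f_plus",
    "f_minus",
    "kernel_value",
    "kernel_fourier",
]

FAMILIES = ("asymmetric_exponential", "symmetric_gaussian")


@dataclass(frozen=True)
class STDPRule:
    """Parameters of a pairwise additive STDP rule.

    tau_plus/tau_minus are the potentiation/depression timescales in
    seconds, ``mu`` in [0, 1] sets the weight-dependence nonlinearity,
    ``alpha`` > 0 the relative strength of depression and ``lam`` > 0 the
    learning rate.
    """

    family: str
    tau_plus: float
    tau_minus: float
    mu: float
    alpha: float
    lam: float

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("kernel timescales must be positive")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.lam <= 0:
            raise ValueError("learning rate lam must be positive")
        if self.tau_minus <= self.tau_plus:
            # depression windows are typically reported wider than
            # potentiation ones; permitted, but worth flagging
            warnings.warn(
                "tau_minus <= tau_plus: depression window narrower than "
                "potentiation window",
                stacklevel=2,
            )


@dataclass(frozen=True)
class KernelFourier:
    """Zeroth moments and first Fourier components of both kernel branches.

    ``k_bar_pm`` are the kernel areas (1 for the built-in families);
    ``k_tilde_pm >= 0`` and ``omega_pm`` are the magnitude and wrapped phase
    of the transform evaluated at angular frequency ``nu``.
    """

    k_bar_plus: float
    k_bar_minus: float
    k_tilde_plus: float
    k_tilde_minus: float
    omega_plus: float
    omega_minus: float
    nu: float


def f_plus(w, mu: float):
    """Potentiation weight dependence ``(1-w)**mu``; ``f_plus(1, 0) = 1``."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("weights must lie in [0, 1]")
    if mu == 0.0:
        return np.ones_like(w)
    return (1.0 - w) ** mu


def f_minus(w, mu: float, alpha: float):
    """Depression weight dependence ``alpha * w**mu``; ``f_minus(0,0) = alpha``."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("weights must lie in [0, 1]")
    if mu == 0.0:
        return np.full_like(w, alpha)
    return alpha * w**mu


def kernel_value(rule: STDPRule, branch: str, dt):
    """Kernel density (1/s) of the given branch ('+' or '-') at lag(s) dt.

    For the asymmetric family the potentiation branch lives on dt > 0 and
    the depression branch on dt < 0; dt = 0 contributes to neither branch
    (spike coincidences are measure-zero in continuous time).  Each branch
    integrates to 1 over the real line.
    """
    if branch not in ("+", "-"):
        raise ValueError("branch must be '+' or '-'")
    dt = np.asarray(dt, dtype=float)
    tau = rule.tau_plus if branch == "+" else rule.tau_minus
    if rule.family == "symmetric_gaussian":
        return np.exp(-0.5 * (dt / tau) ** 2) / (tau * math.sqrt(2.0 * math.pi))
    sign = 1.0 if branch == "+" else -1.0
    out = np.where(sign * dt > 0, np.exp(-np.abs(dt) / tau) / tau, 0.0)
    return out


@lru_cache(maxsize=256)
def _kernel_fourier_cached(
    family: str, tau_plus: float, tau_minus: float, nu: float
) -> KernelFourier:
    if family == "asymmetric_exponential":
        # \int_0^inf e^{-u/tau}/tau e^{-i nu u} du = 1/(1 + i nu tau)
        zp = 1.0 / (1.0 + 1j * nu * tau_plus)
        # \int_-inf^0 e^{u/tau}/tau e^{-i nu u} du = 1/(1 - i nu tau)
        zm = 1.0 / (1.0 - 1j * nu * tau_minus)
    else:
        zp = complex(math.exp(-0.5 * (nu * tau_plus) ** 2))
        zm = complex(math.exp(-0.5 * (nu * tau_minus) ** 2))
    return KernelFourier(
        k_bar_plus=1.0,
        k_bar_minus=1.0,
        k_tilde_plus=abs(zp),
        k_tilde_minus=abs(zm),
        omega_plus=float(wrap_angle(np.angle(zp))),
        omega_minus=float(wrap_angle(np.angle(zm))),
        nu=nu,
    )


def kernel_fourier(rule: STDPRule, nu: float) -> KernelFourier:
    """Closed-form kernel Fourier transforms at angular frequency ``nu``.

    Asymmetric exponential branches give ``1/(1 +- i*nu*tau)``; symmetric
    Gaussians give the real factor ``exp(-(nu*tau)**2/2)`` with zero phase.
    At nu = 0 both branches reduce to the unit kernel area.
    """
    if nu < 0:
        raise ValueError("nu must be non-negative")
    return _kernel_fourier_cached(rule.family, rule.tau_plus, rule.tau_minus, float(nu))
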