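"""Self-consistent fixed points of the mean-field weight dynamics.

Setting the continuum flow to zero (the O(1/N) self term dropped) and
balancing potentiation against depression pointwise yields the stationary
weight profile

    w*(phi) = 1 / (1 + alpha**(1/mu) * ((1 + X_minus)/(1 + X_plus))**(1/mu)),

    X_pm = (w_tilde/w_bar) * (gamma**2/2) * K_tilde_pm
           * cos(phi - nu*d - Omega_pm - psi),

which depends on the order parameters (w_bar, w_tilde, psi) of the very
profile it defines.  The solver closes this loop by damped fixed-point
iteration: given a guess, build the profile on a uniform phase grid,
recompute the order parameters by quadrature against the upstream phase
density, and repeat until the order parameters stop moving.  Trapezoidal
quadrature on the periodic grid is spectrally accurate.

At high whisking frequency both kernel Fourier components vanish, X_pm -> 0,
and the profile collapses to the uniform value ``(1 + alpha**(1/mu))**-1``.
The solver reports existence only; stability is a property of the dynamics
and is assessed by integrating the flow from a perturbed solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rhythmic_model import (
    OrderParameters,
    ThalamicModel,
    VonMisesSpec,
    WeightProfile,
    von_mises_density,
    wrap_angle,
)
from .stdp_rules import STDPRule, f_minus, f_plus, kernel_fourier

__all__ = ["FixedPointResult", "profile_from_order_params", "solve_self_consistent"]


@dataclass(frozen=True)
class FixedPointResult:
    """Converged (or last-iterate) stationary profile and diagnostics.

    ``residual`` is the max |flow| of the continuum dynamics (self term
    excluded) over the grid; ``residual_with_self_term`` adds the O(1/N)
    delta-atom contribution back for reference at finite N.
    """

    phase_grid: np.ndarray
    profile: WeightProfile
    order_params: OrderParameters
    converged: bool
    n_iter: int
    residual: float
    residual_with_self_term: float

    def summary(self) -> dict:
        return {
            "w_bar": self.order_params.w_bar,
            "w_tilde": self.order_params.w_tilde,
            "psi": self.order_params.psi if self.order_params.psi_defined else None,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "residual": self.residual,
            "residual_with_self_term": self.residual_with_self_term,
        }


def uniform_weight(rule: STDPRule) -> float:
    """The phase-independent stationary weight ``(1 + alpha**(1/mu))**-1``."""
    if rule.mu == 0:
        raise ValueError("uniform stationary weight requires mu > 0")
    return 1.0 / (1.0 + rule.alpha ** (1.0 / rule.mu))


def profile_from_order_params(
    op_guess: OrderParameters,
    rule: STDPRule,
    model: ThalamicModel,
    phase_grid: np.ndarray,
) -> WeightProfile:
    """Stationary profile implied by a guess of the order parameters."""
    if rule.mu == 0:
        raise ValueError("the stationary profile requires mu > 0")
    if op_guess.w_bar <= 0:
        raise ValueError("guess must have w_bar > 0")
    phase_grid = np.asarray(phase_grid, dtype=float)
    kf = kernel_fourier(rule, model.nu)
    ratio = op_guess.w_tilde / op_guess.w_bar
    psi = op_guess.psi if op_guess.psi_defined else 0.0
    pref = 0.5 * model.gamma**2 * ratio
    x_plus = pref * kf.k_tilde_plus * np.cos(
        phase_grid - model.nu * model.d - kf.omega_plus - psi
    )
    x_minus = pref * kf.k_tilde_minus * np.cos(
        phase_grid - model.nu * model.d - kf.omega_minus - psi
    )
    if np.any(1.0 + x_plus <= 0):
        raise ValueError("non-physical guess: 1 + X_plus <= 0 on the grid")
    inv_mu = 1.0 / rule.mu
    w = 1.0 / (
        1.0 + rule.alpha**inv_mu * ((1.0 + x_minus) / (1.0 + x_plus)) ** inv_mu
    )
    return WeightProfile(w)


def _grid_order_params(
    w: np.ndarray, phase_grid: np.ndarray, density: np.ndarray
) -> OrderParameters:
    """Order parameters of w(phi) by trapezoid quadrature against Pr(phi)."""
    dphi = phase_grid[1] - phase_grid[0]
    w_bar = float(np.sum(w * density) * dphi)
    z = np.sum(w * density * np.exp(1j * phase_grid)) * dphi
    w_tilde = float(abs(z))
    if w_tilde < 1e-12:
        return OrderParameters(w_bar, 0.0, 0.0, psi_defined=False)
    return OrderParameters(w_bar, w_tilde, float(wrap_angle(np.angle(z))), True)


def _continuum_rhs(
    w: np.ndarray,
    phase_grid: np.ndarray,
    op: OrderParameters,
    rule: STDPRule,
    model: ThalamicModel,
    include_self_term: bool,
) -> np.ndarray:
    from .stdp_rules import kernel_value

    fp = f_plus(w, rule.mu)
    fm = f_minus(w, rule.mu, rule.alpha)
    kf = kernel_fourier(rule, model.nu)
    psi = op.psi if op.psi_defined else 0.0
    shift = model.nu * model.d + psi
    f0 = model.D**2 * (fp - fm)
    f1 = (
        model.D**2
        * 0.5
        * model.gamma**2
        * (
            kf.k_tilde_plus * fp * np.cos(phase_grid - kf.omega_plus - shift)
            - kf.k_tilde_minus * fm * np.cos(phase_grid - kf.omega_minus - shift)
        )
    )
    rhs = op.w_bar * f0 + op.w_tilde * f1
    if include_self_term:
        k_plus_d = float(kernel_value(rule, "+", model.d))
        k_minus_d = float(kernel_value(rule, "-", model.d))
        rhs = rhs + w * (model.D / model.N) * (fp * k_plus_d - fm * k_minus_d)
    return rhs


def solve_self_consistent(
    rule: STDPRule,
    model: ThalamicModel,
    phase_spec: VonMisesSpec,
    init_guess: OrderParameters | None = None,
    damping: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 500,
    n_grid: int = 512,
) -> FixedPointResult:
    """Damped fixed-point iteration for the self-consistent profile.

    Iterates guess -> profile -> order parameters (quadrature against the
    upstream von Mises phase density) with relaxation ``damping`` on
    (w_bar, w_tilde) and circular interpolation on psi.  Non-convergence
    returns the last iterate with ``converged=False`` rather than raising.
    """
    phase_grid = -np.pi + 2.0 * np.pi * np.arange(n_grid) / n_grid
    density = von_mises_density(phase_spec, phase_grid)

    if init_guess is None:
        w0 = uniform_weight(rule)
        init_guess = OrderParameters(w0, 0.1 * w0, phase_spec.psi, True)
    op = init_guess

    converged = False
    n_iter = 0
    profile = profile_from_order_params(op, rule, model, phase_grid)
    for n_iter in range(1, max_iter + 1):
        profile = profile_from_order_params(op, rule, model, phase_grid)
        op_new = _grid_order_params(profile.weights, phase_grid, density)
        # damped update; psi interpolated on the circle to avoid 2*pi jumps
        w_bar = (1 - damping) * op.w_bar + damping * op_new.w_bar
        w_tilde = (1 - damping) * op.w_tilde + damping * op_new.w_tilde
        if op_new.psi_defined and op.psi_defined:
            dpsi = float(wrap_angle(op_new.psi - op.psi))
            psi = float(wrap_angle(op.psi + damping * dpsi))
            psi_ok = True
        else:
            psi, psi_ok = (op_new.psi, op_new.psi_defined)
        delta = max(
            abs(w_bar - op.w_bar),
            abs(w_tilde - op.w_tilde),
            abs(wrap_angle(psi - op.psi)) if psi_ok and op.psi_defined else 0.0,
        )
        op = OrderParameters(w_bar, w_tilde, psi, psi_ok)
        if delta < tol:
            converged = True
            break

    profile = profile_from_order_params(op, rule, model, phase_grid)
    op_final = _grid_order_params(profile.weights, phase_grid, density)
    res = _continuum_rhs(
        profile.weights, phase_grid, op_final, rule, model, include_self_term=False
    )
    res_fd = _continuum_rhs(
        profile.weights, phase_grid, op_final, rule, model, include_self_term=True
    )
    return FixedPointResult(
        phase_grid=phase_grid,
        profile=profile,
        order_params=op_final,
        converged=converged,
        n_iter=n_iter,
        residual=float(np.max(np.abs(res))),
        residual_with_self_term=float(np.max(np.abs(res_fd))),
    )
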