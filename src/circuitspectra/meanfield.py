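"""Stationary mean-field theory: working point and self-consistent rates.

Under the diffusion approximation the recurrent and external Poisson input to
population ``i`` is summarised by its *working point*, the mean ``mu_i`` and
standard deviation ``sigma_i`` of the summed synaptic input (in mV)::

    mu_i      = tau_m * ( sum_j W_ij K_ij r_j + w_ext K_ext_i r_ext )
    sigma_i^2 = tau_m * ( sum_j W_ij^2 K_ij r_j + w_ext^2 K_ext_i r_ext )

The stationary firing rate of a LIF neuron with exponential synaptic currents
driven by such input follows from the stationary solution of the associated
Fokker-Planck equation.  For white noise the first-passage (Siegert) result

    1/nu = tau_ref + tau_m * sqrt(pi) * int_{y_r}^{y_th} e^{s^2} erfc(-s) ds

holds with ``y = (V - mu)/sigma``.  Synaptic filtering (colored noise) is
absorbed, to first order in sqrt(tau_s/tau_m), by shifting threshold and
reset upward by ``sigma * alpha/2 * sqrt(tau_s/tau_m)`` with
``alpha = sqrt(2) |zeta(1/2)|``.

The integrand ``e^{s^2} erfc(-s)`` is evaluated without overflow by splitting
the integration range at zero: on the negative side it equals ``erfcx(|s|)``
(bounded by 1), on the positive side it is written as
``2 e^{s^2} - erfcx(s)`` whose first term integrates to
``sqrt(pi) * erfi(s)`` in closed form.  Beyond ``y_th > 25`` the rate is
below the smallest double and the leading asymptotic term is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfcx, erfi, zetac

from .network import NetworkModel, NeuronParams

__all__ = [
    "WorkingPoint",
    "StationaryState",
    "working_point",
    "siegert_rate",
    "siegert_rate_dmu",
    "solve_selfconsistent",
]

#: boundary-shift constant sqrt(2)*|zeta(1/2)| of the colored-noise correction
ALPHA_SHIFT = np.sqrt(2.0) * abs(zetac(0.5) + 1.0)

# Gauss-Legendre nodes/weights on [0, 1], shared by all integrals
_GL_N = 200
_gl_x, _gl_w = np.polynomial.legendre.leggauss(_GL_N)
_gl_x = 0.5 * (_gl_x + 1.0)
_gl_w = 0.5 * _gl_w


@dataclass(frozen=True)
class WorkingPoint:
    """Per-population mean and standard deviation of the input (mV)."""

    mu: np.ndarray
    sigma: np.ndarray


@dataclass(frozen=True)
class StationaryState:
    """Self-consistent stationary rates with their working point."""

    rates: np.ndarray
    working_point: WorkingPoint
    converged: bool
    residual: float


def working_point(model: NetworkModel, rates) -> WorkingPoint:
    """Mean and std of the synaptic input for given population rates."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    tau_m = model.tau_m_arr()
    ext_mu = model.w_ext * model.K_ext * model.r_ext
    ext_var = model.w_ext**2 * model.K_ext * model.r_ext
    mu = tau_m * ((model.K * model.W) @ rates + ext_mu) + model.ext_mu_offset
    var = tau_m * ((model.K * model.W**2) @ rates + ext_var) + model.ext_var_offset
    return WorkingPoint(mu=mu, sigma=np.sqrt(var))


def _siegert_integral(y_r: float, y_th: float) -> float:
    """int_{y_r}^{y_th} e^{s^2} erfc(-s) ds, overflow-safe for |y| < ~26."""
    total = 0.0
    # negative part: integrand erfcx(-s) <= 1
    a, b = y_r, min(y_th, 0.0)
    if b > a:
        s = a + (b - a) * _gl_x
        total += (b - a) * np.dot(_gl_w, erfcx(-s))
    # positive part: 2 e^{s^2} integrates in closed form via erfi
    a, b = max(y_r, 0.0), y_th
    if b > a:
        s = a + (b - a) * _gl_x
        total += np.sqrt(np.pi) * (erfi(b) - erfi(a))
        total -= (b - a) * np.dot(_gl_w, erfcx(s))
    return total


def siegert_rate(params: NeuronParams, mu: float, sigma: float) -> float:
    """Stationary firing rate (spikes/s) of a LIF neuron at (mu, sigma).

    Includes the sqrt(tau_s/tau_m) threshold/reset shift accounting for the
    synaptic filtering of the input noise.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive (deterministic limit not implemented)")
    shift = 0.5 * ALPHA_SHIFT * np.sqrt(params.tau_s / params.tau_m)
    y_th = (params.V_th - mu) / sigma + shift
    y_r = (params.V_reset - mu) / sigma + shift
    if y_th > 25.0:
        # deeply subthreshold: leading asymptotics of the Siegert integral,
        # 1/nu ~ tau_m sqrt(pi) e^{y^2}/y; underflows to zero gracefully
        return float(y_th * np.exp(-y_th**2) / (params.tau_m * np.sqrt(np.pi)))
    integral = _siegert_integral(y_r, y_th)
    return float(1.0 / (params.tau_ref + params.tau_m * np.sqrt(np.pi) * integral))


def siegert_rate_dmu(params: NeuronParams, mu: float, sigma: float) -> float:
    """Analytic derivative d(siegert_rate)/d(mu) at fixed sigma (1/(s*mV))."""
    nu = siegert_rate(params, mu, sigma)
    if nu == 0.0:
        return 0.0
    shift = 0.5 * ALPHA_SHIFT * np.sqrt(params.tau_s / params.tau_m)
    y_th = (params.V_th - mu) / sigma + shift
    y_r = (params.V_reset - mu) / sigma + shift
    d_int = (erfcx(-y_th) - erfcx(-y_r)) * (-1.0 / sigma)
    return float(-(nu**2) * params.tau_m * np.sqrt(np.pi) * d_int)


def _rate_map(model: NetworkModel, rates: np.ndarray) -> np.ndarray:
    wp = working_point(model, rates)
    return np.array(
        [siegert_rate(p, m, s) for p, m, s in zip(model.neuron, wp.mu, wp.sigma)]
    )


def solve_selfconsistent(
    model: NetworkModel,
    init=None,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    damping: float = 0.05,
) -> StationaryState:
    """Solve the rate self-consistency ``r_i = nu_i(mu(r), sigma(r))``.

    Damped fixed-point iteration (explicit pseudo-time integration of
    ``dr/dt = -r + nu(r)``), which follows the same relaxation dynamics that
    selects the operative low-rate state of the network.  Non-convergence is
    flagged on the result, not raised.
    """
    n = model.n_pop
    rates = np.full(n, 1.0) if init is None else np.asarray(init, dtype=float).copy()
    residual = np.inf
    converged = False
    for _ in range(max_iter):
        target = _rate_map(model, rates)
        residual = float(np.max(np.abs(target - rates)))
        if residual < tol:
            converged = True
            rates = target
            break
        rates = rates + damping * (target - rates)
    wp = working_point(model, rates)
    return StationaryState(
        rates=rates, working_point=wp, converged=converged, residual=residual
    )
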