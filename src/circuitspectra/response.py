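"""Linear response: population transfer functions and effective connectivity.

The dynamical response of a population of LIF neurons with exponential
synaptic currents to a weak modulation of its mean input is described by the
colored-noise linear-response transfer function.  It is expressed through the
parabolic cylinder function ``U(z, x)`` via

    Psi(z, x)   = exp(x^2/4) U(z, -x),
    dPsi(z, x)  = (1/2 + z) Psi(z + 1, x),

    H(omega) = nu0 * sqrt(2)/sigma / (1 + i omega tau_m)
               * (dPsi(z, x_th) - dPsi(z, x_r))
               / ( Psi(z, x_th) -  Psi(z, x_r)),

with ``z = -1/2 + i omega tau_m`` and ``x = sqrt(2) (V_shifted - mu)/sigma``;
threshold and reset are shifted upward by ``sigma alpha/2 sqrt(tau_s/tau_m)``
exactly as in the stationary rate.  At ``omega -> 0`` this reduces to the
derivative of the stationary rate with respect to the mean input.  The rate
modulation arrives through the synapse, which contributes an additional
low-pass ``1/(1 + i omega tau_s)``.

The effective connectivity combines anatomy, response and delays::

    Md_ij(omega) = H_i(omega) * tau_m_i * W_ij * K_ij * B_ij(omega),

where ``B_ij`` is the characteristic function of the zero-truncated Gaussian
delay distribution (mean ``d_ij``, width ``sigma_d_ij``), computed through the
Faddeeva function so that the Gaussian factor and the complementary error
function cannot overflow against each other.  All entries are dimensionless
and reduce at zero frequency to the static gain of the stationary rate map
through the mean-input channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import mpmath
import numpy as np
from scipy.special import erfc, wofz

from .meanfield import ALPHA_SHIFT, StationaryState, siegert_rate, siegert_rate_dmu
from .network import NetworkModel, NeuronParams

__all__ = [
    "FrequencyGrid",
    "TransferFunctions",
    "EffectiveConnectivity",
    "transfer_function",
    "transfer_function_at",
    "anatomical_matrix",
    "delay_factor",
    "effective_connectivity",
    "effective_connectivity_at",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Shared, strictly increasing frequency grid including zero."""

    freqs: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 1 or f.size < 2:
            raise ValueError("frequency grid must be a 1-d array")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if f[0] != 0.0:
            raise ValueError("frequency grid must include 0")
        object.__setattr__(self, "freqs", f)

    @classmethod
    def default(cls, f_max: float = 500.0, df: float = 1.0) -> "FrequencyGrid":
        return cls(np.arange(0.0, f_max + df / 2, df))

    @property
    def omegas(self) -> np.ndarray:
        return 2.0 * np.pi * self.freqs

    def __len__(self):
        return len(self.freqs)


@dataclass(frozen=True)
class TransferFunctions:
    """Per-population complex response H_i(omega) on a grid; shape (F, N)."""

    grid: FrequencyGrid
    H: np.ndarray


@dataclass(frozen=True)
class EffectiveConnectivity:
    """Effective connectivity Md(omega), shape (F, N, N), dimensionless."""

    grid: FrequencyGrid
    Md: np.ndarray
    model: NetworkModel
    state: StationaryState


def _psi(z: complex, x: complex) -> complex:
    return complex(mpmath.exp(0.25 * x * x) * mpmath.pcfu(z, -x))


def _d_psi(z: complex, x: complex) -> complex:
    return (0.5 + z) * _psi(z + 1, x)


def transfer_function_at(
    params: NeuronParams,
    mu: float,
    sigma: float,
    omega: complex,
    colored: bool = True,
    synaptic_filter: bool = True,
) -> complex:
    """Transfer function at a single (possibly complex) angular frequency.

    Rate-modulation amplitude per unit modulation of the mean input
    (units 1/(s*mV)).  ``colored=False`` disables the synaptic low-pass
    (the bare boundary-shifted white-noise response) for cross-checks.
    Complex ``omega`` analytically continues the response into the Laplace
    domain; the parabolic cylinder function is entire in its order.
    """
    shift = 0.5 * ALPHA_SHIFT * np.sqrt(params.tau_s / params.tau_m) * sigma
    if omega == 0:
        return complex(siegert_rate_dmu(params, mu, sigma))
    x_th = np.sqrt(2.0) * (params.V_th + shift - mu) / sigma
    x_r = np.sqrt(2.0) * (params.V_reset + shift - mu) / sigma
    z = -0.5 + 1j * omega * params.tau_m
    try:
        num = _d_psi(z, x_th) - _d_psi(z, x_r)
        den = _psi(z, x_th) - _psi(z, x_r)
    except (ValueError, mpmath.libmp.NoConvergence) as err:
        raise ArithmeticError(
            f"parabolic cylinder evaluation failed at omega={omega!r}"
        ) from err
    nu0 = siegert_rate(params, mu, sigma)
    # refractory occupancy: only the non-refractory fraction (1 - nu*tau_ref)
    # responds; this makes the omega->0 limit agree exactly with d(nu)/d(mu)
    # of the refractory stationary rate.
    occupancy = 1.0 - nu0 * params.tau_ref
    h = (
        np.sqrt(2.0)
        / sigma
        * nu0
        * occupancy
        / (1.0 + 1j * omega * params.tau_m)
        * (num / den)
    )
    if colored and synaptic_filter:
        h = h / (1.0 + 1j * omega * params.tau_s)
    return complex(h)


def transfer_function(
    params_list,
    mu,
    sigma,
    grid: FrequencyGrid,
    colored: bool = True,
) -> TransferFunctions:
    """Transfer functions of all populations over a frequency grid."""
    params_list = list(params_list)
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    n = len(params_list)
    H = np.empty((len(grid), n), dtype=complex)
    for j, (p, m, s) in enumerate(zip(params_list, mu, sigma)):
        for k, w in enumerate(grid.omegas):
            H[k, j] = transfer_function_at(p, m, s, w, colored=colored)
    return TransferFunctions(grid=grid, H=H)


def anatomical_matrix(model: NetworkModel) -> np.ndarray:
    """Anatomical connectivity: elementwise product of indegrees and weights."""
    return model.K * model.W


def delay_factor(d: float, sigma_d: float, omega: complex):
    """Characteristic function of the zero-truncated Gaussian delay density.

    ``E[exp(-i omega y)]`` for a Gaussian with mean ``d`` (s) and std
    ``sigma_d`` (s) truncated to ``y >= 0``.  For ``sigma_d = 0`` this is the
    pure phase factor ``exp(-i omega d)``.  Entire in ``omega``, so complex
    frequencies are evaluated directly.
    """
    if sigma_d < 0 or d < 0:
        raise ValueError("delay mean and std must be non-negative")
    omega = np.asarray(omega)
    if sigma_d**2 == 0.0:  # exactly zero or underflowing: point-mass limit
        return np.exp(-1j * omega * d)
    if d / sigma_d > 8.0:
        # truncated mass < 1e-15: the plain Gaussian characteristic function
        # is exact to machine precision and avoids 0*inf in the ratio form
        return np.exp(-1j * omega * d - 0.5 * sigma_d**2 * omega**2)
    # E[e^{-iwy}] = e^{-iwd} e^{-s^2 w^2/2} * erfc(zeta)/erfc(-d/(s sqrt2))
    # with zeta = (-d + i w s^2)/(s sqrt2).  Writing erfc through the
    # Faddeeva function w(z) cancels the Gaussian factors analytically:
    zeta = (-d + 1j * omega * sigma_d**2) / (sigma_d * np.sqrt(2.0))
    norm = erfc(-d / (sigma_d * np.sqrt(2.0)))
    return np.exp(-d**2 / (2.0 * sigma_d**2)) * wofz(1j * zeta) / norm


def _delay_matrix(model: NetworkModel, omega: complex) -> np.ndarray:
    n = model.n_pop
    out = np.empty((n, n), dtype=complex)
    for i in range(n):
        for j in range(n):
            out[i, j] = delay_factor(model.d_mean[i, j], model.d_std[i, j], omega)
    return out


def effective_connectivity(
    model: NetworkModel,
    state: StationaryState,
    tf: TransferFunctions,
    grid: FrequencyGrid,
) -> EffectiveConnectivity:
    """Assemble Md(omega) = H_i * tau_m_i * (K*W)_ij * delay_ij on the grid."""
    if tf.grid is not grid and not np.array_equal(tf.grid.freqs, grid.freqs):
        raise ValueError("transfer functions were computed on a different grid")
    MA = anatomical_matrix(model)
    tau_m = model.tau_m_arr()
    F, n = len(grid), model.n_pop
    B = np.empty((F, n, n), dtype=complex)
    for i in range(n):
        for j in range(n):
            B[:, i, j] = delay_factor(model.d_mean[i, j], model.d_std[i, j], grid.omegas)
    Md = (tf.H * tau_m)[:, :, None] * MA[None, :, :] * B
    return EffectiveConnectivity(grid=grid, Md=Md, model=model, state=state)


def effective_connectivity_at(
    model: NetworkModel,
    state: StationaryState,
    omega: complex,
    colored: bool = True,
) -> np.ndarray:
    """Single-frequency Md(omega); supports complex omega (Laplace domain)."""
    wp = state.working_point
    MA = anatomical_matrix(model)
    tau_m = model.tau_m_arr()
    H = np.array(
        [
            transfer_function_at(p, m, s, omega, colored=colored)
            for p, m, s in zip(model.neuron, wp.mu, wp.sigma)
        ]
    )
    return (H * tau_m)[:, None] * MA * _delay_matrix(model, omega)
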