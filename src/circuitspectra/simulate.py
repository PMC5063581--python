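"""Stochastic simulation of the delayed linear rate model.

This module provides a numerical oracle that is independent of the
frequency-domain propagator algebra: the time-domain convolution system

    r_i(t) = sum_j ( g_ij * y_j )(t),      y_j = r_j + x_j,

is integrated explicitly (Euler-Maruyama), with white noise
``<x_i(s) x_j(t)> = delta_ij delta(s-t) rbar_i/M_i`` representing the
Poisson realisation of spiking.  The connection kernels

    g_ij(t) = MA_ij * (h_i * p_ij)(t)

combine the population impulse response ``h_i`` (inverse Fourier transform
of the transfer function, evaluated on a dense FFT grid) with the delay
density ``p_ij``.  In the default *averaged-kernel* mode ``p_ij`` is the
zero-truncated Gaussian density itself, making the simulated system exactly
the one whose spectra the analytic pipeline predicts; in *per-draw* mode
delays are sampled once per connection pair for realism checks.

Welch periodograms of the simulated traces are returned in two-sided
density units, directly comparable to the analytic C(omega).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import signal as sp_signal

from .meanfield import StationaryState
from .network import NetworkModel
from .response import FrequencyGrid, delay_factor, transfer_function_at

__all__ = ["RateTrace", "simulate", "periodogram", "connection_kernels"]


@dataclass
class RateTrace:
    """Simulated fluctuating population rates (spikes/s around zero mean)."""

    dt: float  # s
    duration: float  # s
    y: np.ndarray  # (steps, N)
    seed: int


@njit(cache=True)
def _integrate(x: np.ndarray, G: np.ndarray, A: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoidal update of y = x + g * y.

    ``G[m-1]`` holds the kernel at lag m*dt; the t=0 half-weight is treated
    implicitly through ``A = (I - dt/2 * g(0))^-1``::

        y[t] = A @ ( x[t] + dt * sum_{m=1..L} G[m-1] @ y[t-m] ).
    """
    steps, n = x.shape
    L = G.shape[0]
    y = np.zeros((steps, n))
    acc = np.zeros(n)
    for t in range(steps):
        mmax = min(L, t)
        for i in range(n):
            s = x[t, i]
            for m in range(1, mmax + 1):
                row = G[m - 1, i]
                past = y[t - m]
                for j in range(n):
                    s += row[j] * past[j] * dt
            acc[i] = s
        for i in range(n):
            s = 0.0
            for j in range(n):
                s += A[i, j] * acc[j]
            y[t, i] = s
    return y


def _impulse_response(model, pop, mu, sigma, dt, n_fft) -> np.ndarray:
    """h_i(t) on the time grid via inverse FFT of the transfer function."""
    freqs = np.fft.rfftfreq(n_fft, dt)
    H = np.empty(len(freqs), dtype=complex)
    p = model.neuron[pop]
    for k, f in enumerate(freqs):
        H[k] = transfer_function_at(p, mu, sigma, 2 * np.pi * f)
    return np.fft.irfft(H, n=n_fft) / dt


def connection_kernels(
    model: NetworkModel,
    state: StationaryState,
    dt: float,
    kernel_cut: float = 1e-6,
    delay_mode: str = "averaged",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Causal kernels g_ij sampled at t = dt, 2dt, ...; shape (L, N, N).

    Kernels are truncated where all entries fall below ``kernel_cut`` times
    the overall maximum.
    """
    n = model.n_pop
    tau_m = model.tau_m_arr()
    wp = state.working_point
    t_kernel = 0.2  # s; long compared to tau_m and delays
    n_fft = int(round(t_kernel / dt))
    freqs = np.fft.rfftfreq(n_fft, dt)
    omegas = 2 * np.pi * freqs
    G_freq = np.zeros((len(freqs), n, n), dtype=complex)
    # H is smooth (scales tau_m, tau_s): evaluate on a sparse node grid,
    # dense at low frequency, and spline onto the FFT grid
    f_max = freqs[-1]
    nodes = np.unique(np.concatenate([
        np.arange(0.0, min(500.0, f_max), 5.0),
        np.arange(500.0, f_max, 100.0),
        [f_max],
    ]))
    H_nodes = np.empty((len(nodes), n), dtype=complex)
    for i in range(n):
        for k, fn in enumerate(nodes):
            H_nodes[k, i] = transfer_function_at(
                model.neuron[i], wp.mu[i], wp.sigma[i], 2 * np.pi * fn
            )
    from scipy.interpolate import CubicSpline

    H = CubicSpline(nodes, H_nodes, axis=0)(freqs)
    if delay_mode == "averaged":
        for i in range(n):
            for j in range(n):
                B = delay_factor(model.d_mean[i, j], model.d_std[i, j], omegas)
                G_freq[:, i, j] = H[:, i] * tau_m[i] * model.K[i, j] * model.W[i, j] * B
    elif delay_mode == "per_draw":
        if rng is None:
            rng = np.random.default_rng()
        for i in range(n):
            for j in range(n):
                d = -1.0
                while d < 0:
                    d = rng.normal(model.d_mean[i, j], model.d_std[i, j])
                B = np.exp(-1j * omegas * d)
                G_freq[:, i, j] = H[:, i] * tau_m[i] * model.K[i, j] * model.W[i, j] * B
    else:
        raise ValueError(f"unknown delay_mode {delay_mode!r}")
    g = np.fft.irfft(G_freq, n=n_fft, axis=0) / dt  # (n_fft, N, N)
    peak = np.max(np.abs(g))
    if peak == 0:
        return np.zeros((2, n, n))
    keep = np.where(np.max(np.abs(g), axis=(1, 2)) > kernel_cut * peak)[0]
    L = int(keep[-1]) + 1 if len(keep) else 1
    L = min(L, n_fft // 2)  # guard against wrap-around tail
    # samples at t = 0, dt, ..., L*dt; the t=0 value enters the trapezoidal
    # update with half weight (the synaptic component and broad delay
    # densities carry real mass at zero lag)
    return g[: L + 1].copy()


def simulate(
    model: NetworkModel,
    state: StationaryState,
    duration: float,
    dt: float = 1e-4,
    seed: int = 0,
    delay_mode: str = "averaged",
    check_stability: bool = True,
) -> RateTrace:
    """Integrate the delayed linear rate model driven by Poisson-like noise.

    Refuses unstable circuits (any eigenvalue of the effective connectivity
    with real part >= 1 near the real axis); see the stability module for
    analysis of such circuits.
    """
    tau_s_min = model.tau_s_arr().min()
    if dt > tau_s_min / 5:
        raise ValueError(f"dt={dt} too coarse; need <= tau_s/5 = {tau_s_min / 5:g}")
    if check_stability:
        from .response import effective_connectivity, transfer_function
        from .sensitivity import _is_stable

        grid = FrequencyGrid.default(500.0, 5.0)
        tf = transfer_function(
            model.neuron, state.working_point.mu, state.working_point.sigma, grid
        )
        if not _is_stable(effective_connectivity(model, state, tf, grid)):
            raise RuntimeError(
                "circuit is linearly unstable; inspect it with the stability module"
            )
    rng = np.random.default_rng(seed)
    g = connection_kernels(model, state, dt, delay_mode=delay_mode, rng=rng)
    A = np.linalg.inv(np.eye(model.n_pop) - 0.5 * dt * g[0])
    steps = int(round(duration / dt))
    D = state.rates / model.sizes
    x = rng.standard_normal((steps, model.n_pop)) * np.sqrt(D / dt)
    y = _integrate(x, np.ascontiguousarray(g[1:]), np.ascontiguousarray(A), dt)
    return RateTrace(dt=dt, duration=duration, y=y, seed=seed)


def periodogram(
    trace: RateTrace, window: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch-averaged two-sided spectral density with standard errors.

    ``window`` is the segment length in seconds.  Returns
    ``(freqs, C, stderr)`` where ``C[k, i]`` estimates the analytic
    ``C_ii(2 pi f_k)`` in (spikes/s)^2 * s and ``stderr`` is the per-bin
    chi^2 standard error ``C / sqrt(n_segments)``.
    """
    nper = int(round(window / trace.dt))
    steps = trace.y.shape[0]
    if nper > steps:
        raise ValueError("window longer than the simulated trace")
    n_seg = steps // nper
    if n_seg < 2:
        raise ValueError("need at least two windows for averaging")
    f, Pxx = sp_signal.welch(
        trace.y,
        fs=1.0 / trace.dt,
        window="boxcar",
        nperseg=nper,
        noverlap=0,
        detrend="constant",
        scaling="density",
        axis=0,
    )
    # welch returns one-sided density (doubled except DC/Nyquist); convert
    # to the two-sided convention of the analytic C(omega)
    C = Pxx / 2.0
    C[0] *= 2.0
    if nper % 2 == 0:
        C[-1] *= 2.0
    return f, C, C / np.sqrt(n_seg)
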