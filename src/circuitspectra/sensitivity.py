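"""Sensitivity of the critical eigenvalue to individual connections.

A fractional perturbation ``alpha`` of a single indegree ``K_kl`` scales the
``kl`` element of the effective connectivity by ``(1 + alpha)``.  For a
simple eigenvalue ``lambda_c`` with bi-orthonormal left/right eigenvectors
``v_c, u_c`` first-order perturbation theory gives the sensitivity

    Z_kl(omega) = v_{c,k} Md_kl(omega) u_{c,l} / (v_c^T u_c),

so the perturbed eigenvalue moves as ``lambda_c + Z_kl * alpha`` to linear
order.  Because the spectral peak height is controlled by the distance of
``lambda_c`` to the critical value 1, the complex entries of ``Z`` are
projected onto the unit vector ``k`` pointing from ``lambda_c`` toward 1
(controls peak *amplitude*) and its perpendicular ``k_perp`` (controls peak
*frequency*)::

    Z_amp = Re(Z) k_x + Im(Z) k_y,     Z_freq = Re(Z) kp_x + Im(Z) kp_y.

``minimal_circuit`` greedily keeps the connections with the largest |Z_amp|
and |Z_freq| entries (guarding against destabilising the reduced circuit)
and rebuilds the spectra with all other connections replaced by equivalent
uncorrelated external input, quantifying how much of the peak the retained
sub-circuit reproduces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .modes import ModeDecomposition, closest_approach, decompose
from .network import NetworkModel, isolate_subcircuit
from .response import EffectiveConnectivity, effective_connectivity
from .spectra import SpectraResult, find_peaks, noise_matrix, power_spectra

__all__ = [
    "SensitivityMap",
    "sensitivity",
    "linear_shift",
    "project_amp_freq",
    "sensitivity_at_peak",
    "minimal_circuit",
    "MinimalCircuitResult",
]

logger = logging.getLogger(__name__)


@dataclass
class SensitivityMap:
    """Connection-resolved sensitivity of one mode at one frequency."""

    frequency: float
    mode: int
    lambda_c: complex
    Z: np.ndarray
    Z_amp: np.ndarray | None = None
    Z_freq: np.ndarray | None = None
    k: np.ndarray | None = None
    k_perp: np.ndarray | None = None
    labels: list | None = None


def sensitivity(
    Md_omega: np.ndarray,
    decomp_u: np.ndarray,
    decomp_v: np.ndarray,
    mode: int,
    frequency: float = np.nan,
    lambda_c: complex | None = None,
    labels=None,
) -> SensitivityMap:
    """Sensitivity matrix of one mode from a single-frequency decomposition.

    ``decomp_u``/``decomp_v`` are the (N, N) eigenvector matrices at this
    frequency (columns = modes).
    """
    u = decomp_u[:, mode]
    v = decomp_v[:, mode]
    vu = v @ u
    if abs(vu) < 1e-12:
        raise ValueError("left/right eigenvectors are not normalizable (v^T u ~ 0)")
    Z = np.outer(v, u) * Md_omega / vu
    if lambda_c is None:
        lambda_c = complex(v @ Md_omega @ u / vu)
    smap = SensitivityMap(
        frequency=frequency, mode=mode, lambda_c=lambda_c, Z=Z, labels=labels
    )
    project_amp_freq(smap)
    return smap


def sensitivity_from_decomposition(
    Md: EffectiveConnectivity, decomp: ModeDecomposition, mode: int, frequency: float
) -> SensitivityMap:
    """Sensitivity map of a tracked mode at the grid point nearest a frequency."""
    k = int(np.argmin(np.abs(Md.grid.freqs - frequency)))
    return sensitivity(
        Md.Md[k],
        decomp.u[k],
        decomp.v[k],
        mode,
        frequency=Md.grid.freqs[k],
        lambda_c=decomp.lambdas[k, mode],
        labels=list(Md.model.labels),
    )


def linear_shift(smap: SensitivityMap, target: int, source: int, alpha: float) -> complex:
    """First-order prediction of the perturbed eigenvalue."""
    return smap.lambda_c + smap.Z[target, source] * alpha


def project_amp_freq(smap: SensitivityMap) -> tuple[np.ndarray, np.ndarray]:
    """Project Z onto the amplitude (toward 1) and frequency directions."""
    lam = smap.lambda_c
    dx, dy = 1.0 - lam.real, lam.imag
    norm = np.hypot(dx, dy)
    if norm == 0:
        raise ValueError("critical eigenvalue equals 1: projection undefined")
    k = np.array([dx, dy]) / norm
    k_perp = np.array([-dy, dx]) / norm
    smap.k, smap.k_perp = k, k_perp
    smap.Z_amp = smap.Z.real * k[0] + smap.Z.imag * k[1]
    smap.Z_freq = smap.Z.real * k_perp[0] + smap.Z.imag * k_perp[1]
    return smap.Z_amp, smap.Z_freq


def _dominant_mode_at(decomp: ModeDecomposition, freq: float) -> int:
    k = int(np.argmin(np.abs(decomp.grid.freqs - freq)))
    return int(np.argmin(np.abs(1.0 - decomp.lambdas[k])))


def sensitivity_at_peak(
    Md: EffectiveConnectivity,
    D: np.ndarray,
    band: tuple[float, float] | None,
    decomp: ModeDecomposition | None = None,
) -> SensitivityMap:
    """Locate the spectral peak in ``band`` and return its sensitivity map.

    ``band=None`` (or a degenerate band at 0) analyses zero frequency: the
    map of the mode closest to criticality there, governing slow rate
    fluctuations and the stability of the stationary state.
    """
    if decomp is None:
        decomp = decompose(Md)
    if band is None or (band[0] == 0 and band[1] == 0):
        mode = _dominant_mode_at(decomp, 0.0)
        return sensitivity_from_decomposition(Md, decomp, mode, 0.0)
    spectra = power_spectra(Md, D)
    peaks = find_peaks(spectra, band)
    if not peaks:
        raise ValueError(f"no spectral peak found in band {band}")
    f_peak = peaks[0][0]
    mode = _dominant_mode_at(decomp, f_peak)
    return sensitivity_from_decomposition(Md, decomp, mode, f_peak)


@dataclass
class MinimalCircuitResult:
    """Reduced circuit extracted from a sensitivity map, with recovery metrics."""

    mask: np.ndarray
    model: NetworkModel
    spectra: SpectraResult
    peak_freq_full: np.ndarray
    peak_freq_reduced: np.ndarray
    freq_recovery: np.ndarray  # percent, per participating population
    logamp_recovery: np.ndarray  # percent
    participating: np.ndarray  # boolean, populations touched by the mask


def _is_stable(Md: EffectiveConnectivity, im_tol: float = 0.05) -> bool:
    """Reject circuits whose eigenvalue trajectories reach Re >= 1 near the
    real axis anywhere on the grid (onset of sustained oscillations or rate
    instability)."""
    for k in range(len(Md.grid)):
        lam = np.linalg.eigvals(Md.Md[k])
        if np.any((lam.real >= 1.0) & (np.abs(lam.imag) < im_tol)):
            return False
    return True


def minimal_circuit(
    model: NetworkModel,
    smap: SensitivityMap,
    n_amp: int,
    n_freq: int,
    state,
    tf,
    band: tuple[float, float] = (30.0, 90.0),
    check_stability: bool = True,
) -> MinimalCircuitResult:
    """Extract the sub-circuit with the strongest influence on a peak.

    Keeps the union of the ``n_amp`` largest |Z_amp| and ``n_freq`` largest
    |Z_freq| entries (existing connections only).  If the resulting reduced
    circuit is unstable, the offending candidate is skipped and the next
    entry in the ranking is taken.  All removed connections are replaced by
    external drive with identical mean and variance, so every population
    keeps its working point; recovery is quantified per participating
    population as

      - frequency recovery: 100 * min(f_red, f_full) / max(f_red, f_full)
      - log-amplitude recovery: same ratio on log10(peak power / baseline),
        baseline being the flat Poisson level rbar/M.
    """
    n = model.n_pop
    if max(n_amp, n_freq) > n * n:
        raise ValueError("requested more connections than exist")
    D = noise_matrix(state, model.sizes)
    Md_full = effective_connectivity(model, state, tf, tf.grid)
    spec_full = power_spectra(Md_full, D)

    exists = model.K > 0

    def ranked(M):
        order = np.argsort(-np.abs(M), axis=None)
        return [divmod(int(o), n) for o in order if exists[divmod(int(o), n)]]

    def build(mask):
        red = isolate_subcircuit(model, mask, state.rates)
        return red, effective_connectivity(red, state, tf, tf.grid)

    mask = np.zeros((n, n), dtype=bool)
    for M, n_want in ((smap.Z_amp, n_amp), (smap.Z_freq, n_freq)):
        taken = 0
        for i, j in ranked(M):
            if taken >= n_want:
                break
            if mask[i, j]:
                taken += 1  # already kept by the other ranking
                continue
            mask[i, j] = True
            if check_stability:
                _, Md_try = build(mask)
                if not _is_stable(Md_try):
                    logger.info(
                        "minimal_circuit: skipping destabilising connection %s<-%s",
                        model.labels[i],
                        model.labels[j],
                    )
                    mask[i, j] = False
                    continue
            taken += 1

    red_model, Md_red = build(mask)
    spec_red = power_spectra(Md_red, D)
    baseline = state.rates / model.sizes
    participating = mask.any(axis=1) | mask.any(axis=0)
    f_full = np.full(n, np.nan)
    f_red = np.full(n, np.nan)
    freq_rec = np.full(n, np.nan)
    amp_rec = np.full(n, np.nan)
    for i in range(n):
        pk_full = find_peaks(spec_full, band, population=i)
        pk_red = find_peaks(spec_red, band, population=i)
        if not pk_full or not pk_red:
            continue
        f_full[i], h_full = pk_full[0]
        f_red[i], h_red = pk_red[0]
        freq_rec[i] = 100.0 * min(f_full[i], f_red[i]) / max(f_full[i], f_red[i])
        L_full = np.log10(h_full / baseline[i])
        L_red = np.log10(h_red / baseline[i])
        if L_full > 0 and L_red > 0:
            amp_rec[i] = 100.0 * min(L_full, L_red) / max(L_full, L_red)
    return MinimalCircuitResult(
        mask=mask,
        model=red_model,
        spectra=spec_red,
        peak_freq_full=f_full,
        peak_freq_reduced=f_red,
        freq_recovery=freq_rec,
        logamp_recovery=amp_rec,
        participating=participating,
    )
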