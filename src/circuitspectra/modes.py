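"""Eigenmode decomposition of the effective connectivity across frequency.

At every frequency the effective connectivity is diagonalised,

    Md(omega) u_i(omega) = lambda_i(omega) u_i(omega),
    v_i(omega)^T Md(omega) = lambda_i(omega) v_i(omega)^T,

with the bi-orthonormal convention ``v_i^T u_i = 1``.  Because the
decomposition is computed independently per frequency, eigenpairs are
relabeled across neighbouring grid points so that each eigenvalue traces a
continuous trajectory lambda_i(omega) in the complex plane: modes are
matched greedily by largest left-right eigenvector overlap
``|v_i(omega_k)^T u_j(omega_{k+1})|``, falling back to nearest-eigenvalue
matching when the overlap is ambiguous (near-degenerate crossings).

The propagator shares the eigenvectors, with eigenvalues
``1/(1 - lambda_i)``; the factor ``p(omega) = 1/|1 - lambda_i(omega)|``
therefore controls how strongly mode ``i`` amplifies the intrinsic noise at
each frequency, and the point where a trajectory comes closest to the
critical value 1 marks the resonance of that mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .response import EffectiveConnectivity, FrequencyGrid

__all__ = [
    "ModeDecomposition",
    "decompose",
    "p_factor",
    "closest_approach",
    "mode_spectrum_approx",
    "mode_pair_spectra",
]

logger = logging.getLogger(__name__)

#: overlap below which greedy eigenvector matching falls back to nearest-lambda
OVERLAP_THRESHOLD = 0.5


@dataclass
class ModeDecomposition:
    """Tracked eigenmodes of Md(omega).

    ``lambdas[f, i]`` is the eigenvalue of mode ``i`` at grid point ``f``;
    ``u[f, :, i]`` / ``v[f, :, i]`` the right/left eigenvectors, normalised
    to ``v_i^T u_i = 1``.  Mode indices are consistent across frequency.
    """

    grid: FrequencyGrid
    lambdas: np.ndarray  # (F, N)
    u: np.ndarray  # (F, N, N)
    v: np.ndarray  # (F, N, N)

    @property
    def n_modes(self) -> int:
        return self.lambdas.shape[1]


def _eig_biorthonormal(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decomposition with v_i^T u_i = 1 per mode."""
    lam, u = np.linalg.eig(M)
    # left eigenvectors: rows of inv(u) satisfy v_i^T M = lam_i v_i^T and
    # v_i^T u_j = delta_ij already
    v = np.linalg.inv(u).T
    return lam, u, v


def decompose(Md: EffectiveConnectivity) -> ModeDecomposition:
    """Diagonalise Md at each frequency and track modes continuously."""
    F, n, _ = Md.Md.shape
    lambdas = np.empty((F, n), dtype=complex)
    us = np.empty((F, n, n), dtype=complex)
    vs = np.empty((F, n, n), dtype=complex)
    lam, u, v = _eig_biorthonormal(Md.Md[0])
    order = np.argsort(-lam.real)  # seed ordering by descending real part
    lam, u, v = lam[order], u[:, order], v[:, order]
    lambdas[0], us[0], vs[0] = lam, u, v
    for k in range(1, F):
        lam_new, u_new, v_new = _eig_biorthonormal(Md.Md[k])
        # overlap of previous left with new right eigenvectors
        overlap = np.abs(vs[k - 1].T @ u_new)  # (prev_mode, new_mode)
        perm = np.full(n, -1)
        used = np.zeros(n, dtype=bool)
        pairs = sorted(
            ((overlap[i, j], i, j) for i in range(n) for j in range(n)),
            key=lambda t: -t[0],
        )
        for ov, i, j in pairs:
            if perm[i] == -1 and not used[j]:
                if ov < OVERLAP_THRESHOLD:
                    break
                perm[i] = j
                used[j] = True
        if np.any(perm == -1):
            # ambiguous overlaps: match leftover modes by eigenvalue distance
            logger.debug(
                "mode tracking: overlap fallback at f = %g Hz", Md.grid.freqs[k]
            )
            for i in np.where(perm == -1)[0]:
                dists = np.abs(lam_new - lambdas[k - 1, i])
                dists[used] = np.inf
                j = int(np.argmin(dists))
                perm[i] = j
                used[j] = True
        lambdas[k] = lam_new[perm]
        us[k] = u_new[:, perm]
        vs[k] = v_new[:, perm]
    return ModeDecomposition(grid=Md.grid, lambdas=lambdas, u=us, v=vs)


def p_factor(lambda_traj: np.ndarray) -> np.ndarray:
    """Noise-amplification factor 1/|1 - lambda| along a trajectory."""
    dist = np.abs(1.0 - np.asarray(lambda_traj))
    with np.errstate(divide="ignore"):
        p = 1.0 / dist
    if np.any(~np.isfinite(p)):
        logger.warning("p_factor: eigenvalue exactly 1 on the grid")
    return p


def closest_approach(
    lambda_traj: np.ndarray,
    grid: FrequencyGrid,
    band: tuple[float, float] | None = None,
) -> tuple[float, float, str]:
    """Frequency where a trajectory comes closest to 1, with side label.

    Returns ``(frequency, distance, side)`` where ``side`` is ``"left"`` if
    the real part of the closest eigenvalue is below 1 and ``"right"``
    otherwise.  The minimum of ``|1 - lambda|`` is refined by a quadratic fit
    through the three neighbouring grid points.
    """
    f = grid.freqs
    lam = np.asarray(lambda_traj)
    sel = np.arange(len(f))
    if band is not None:
        sel = np.where((f >= band[0]) & (f <= band[1]))[0]
        if sel.size == 0:
            raise ValueError("band contains no grid points")
    d = np.abs(1.0 - lam[sel])
    k_loc = int(np.argmin(d))
    k = sel[k_loc]
    side = "left" if lam[k].real < 1.0 else "right"
    if 0 < k < len(f) - 1:
        dm, d0, dp = np.abs(1 - lam[k - 1]), np.abs(1 - lam[k]), np.abs(1 - lam[k + 1])
        denom = dm - 2 * d0 + dp
        if denom > 0:
            delta = 0.5 * (dm - dp) / denom
            delta = np.clip(delta, -1, 1)
            fk = f[k] + delta * (f[min(k + 1, len(f) - 1)] - f[k])
            dk = d0 - 0.25 * (dm - dp) * delta
            return float(fk), float(dk), side
    return float(f[k]), float(d[k]), side


def mode_pair_spectra(decomp: ModeDecomposition, D: np.ndarray) -> np.ndarray:
    """Full spectrum as a sum over all mode pairs; shape (F, N), real.

    For each frequency,
    ``C_kk = sum_ij beta_ij T_ij,k`` with
    ``beta_ij = (v_i^T D v_j^*) / ((1 - lambda_i)(1 - lambda_j^*))`` and
    ``T_ij = u_i u_j^{*T}``.  Equals the propagator-based spectrum exactly
    when Md is diagonalisable (completeness of the bi-orthogonal basis).
    """
    F, n = decomp.lambdas.shape
    out = np.empty((F, n))
    for k in range(F):
        v = decomp.v[k]
        u = decomp.u[k]
        lam = decomp.lambdas[k]
        alpha = v.T @ D @ np.conj(v)  # alpha_i alpha_j^*
        beta = alpha / np.outer(1.0 - lam, np.conj(1.0 - lam))
        # C_kk = sum_ij beta_ij u_{k,i} u_{k,j}^*
        out[k] = np.real(np.einsum("ij,ki,kj->k", beta, u, np.conj(u)))
    return out


def mode_spectrum_approx(
    decomp: ModeDecomposition,
    D: np.ndarray,
    mode: int,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Single-mode approximation of the population spectra; shape (F, N).

    Keeps only the ``i = j = mode`` term of the mode-pair sum:
    ``C_kk ~ |alpha_c|^2 / |1 - lambda_c|^2 * |u_{c,k}|^2``.  Frequencies
    outside ``window`` are returned as NaN so the approximation is only read
    where the mode dominates.
    """
    F, n = decomp.lambdas.shape
    out = np.full((F, n), np.nan)
    f = decomp.grid.freqs
    sel = np.arange(F)
    if window is not None:
        sel = np.where((f >= window[0]) & (f <= window[1]))[0]
    for k in sel:
        v_c = decomp.v[k][:, mode]
        u_c = decomp.u[k][:, mode]
        lam_c = decomp.lambdas[k, mode]
        alpha2 = np.real(v_c @ D @ np.conj(v_c))
        out[k] = alpha2 / np.abs(1.0 - lam_c) ** 2 * np.abs(u_c) ** 2
    return out
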