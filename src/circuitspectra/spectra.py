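"""Propagator, noise matrix and population rate power spectra.

The observed population activity is the intrinsic Poisson-like noise mapped
through the propagator ``P(omega) = (I - Md(omega))^-1``::

    C(omega) = P(omega) D P^T(-omega),       D_ii = rbar_i / M_i,

and the power spectral density of population ``i`` is the (real,
non-negative) diagonal element ``C_ii``.  Units: (spikes/s)^2 * s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .meanfield import StationaryState
from .response import EffectiveConnectivity, FrequencyGrid

__all__ = [
    "SpectraResult",
    "noise_matrix",
    "propagator",
    "power_spectra",
    "cross_spectra",
    "find_peaks",
    "LOW_GAMMA_BAND",
    "HIGH_GAMMA_BAND",
]

logger = logging.getLogger(__name__)

#: default reporting bands (Hz)
LOW_GAMMA_BAND = (30.0, 90.0)
HIGH_GAMMA_BAND = (150.0, 400.0)


@dataclass
class SpectraResult:
    """Per-population power spectral densities on a frequency grid."""

    grid: FrequencyGrid
    C: np.ndarray  # (F, N) real
    labels: list = field(default_factory=list)

    def population(self, idx) -> np.ndarray:
        if isinstance(idx, str):
            idx = self.labels.index(idx)
        return self.C[:, idx]


def noise_matrix(state: StationaryState, sizes) -> np.ndarray:
    """Diagonal noise-power matrix D with D_ii = rbar_i / M_i."""
    sizes = np.asarray(sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("population sizes must be positive")
    return np.diag(state.rates / sizes)


def propagator(Md: EffectiveConnectivity) -> np.ndarray:
    """(I - Md(omega))^-1 at every grid frequency; shape (F, N, N)."""
    F, n, _ = Md.Md.shape
    eye = np.eye(n)
    P = np.empty_like(Md.Md)
    worst = 0.0
    for k in range(F):
        A = eye - Md.Md[k]
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"I - Md is singular at f = {Md.grid.freqs[k]:g} Hz "
                "(an eigenvalue reaches 1)"
            )
        worst = max(worst, cond)
        P[k] = np.linalg.inv(A)
    logger.debug("propagator: worst condition number %.3g", worst)
    return P


def cross_spectra(Md: EffectiveConnectivity, D: np.ndarray) -> np.ndarray:
    """Full cross-spectral matrices C(omega) = P D P^dagger; (F, N, N)."""
    P = propagator(Md)
    return np.einsum("fij,jk,flk->fil", P, D, np.conj(P))


def power_spectra(Md: EffectiveConnectivity, D: np.ndarray) -> SpectraResult:
    """Per-population power spectral densities (diagonal of C(omega))."""
    C = cross_spectra(Md, D)
    diag = np.real(np.einsum("fii->fi", C))
    # clip tiny negative round-off
    diag = np.where(diag < 0, 0.0, diag)
    return SpectraResult(grid=Md.grid, C=diag, labels=list(Md.model.labels))


def _quadratic_refine(f: np.ndarray, y: np.ndarray, k: int) -> tuple[float, float]:
    """Vertex of the parabola through points k-1, k, k+1 on log-power."""
    x0, x1, x2 = f[k - 1], f[k], f[k + 1]
    y0, y1, y2 = np.log(y[k - 1]), np.log(y[k]), np.log(y[k + 1])
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # degenerate (not a maximum): keep the grid point
        return float(x1), float(y[k])
    fpk = -b / (2 * a)
    ypk = np.exp(y1 + a * (fpk - x1) ** 2 + (b + 2 * a * x1) * (fpk - x1))
    return float(fpk), float(ypk)


def find_peaks(C, band: tuple[float, float], population=None) -> list[tuple[float, float]]:
    """Local spectral maxima in ``band``, refined by quadratic interpolation.

    ``C`` is a :class:`SpectraResult`; ``population`` selects one column
    (index or label), default is the summed spectrum.  Returns
    ``(frequency, height)`` pairs sorted by decreasing height.
    """
    f = C.grid.freqs
    lo, hi = band
    if lo >= hi or lo < f[0] or hi > f[-1]:
        raise ValueError(f"band {band} not contained in grid [{f[0]}, {f[-1]}]")
    if population is None:
        y = C.C.sum(axis=1)
    else:
        y = C.population(population)
    sel = np.where((f >= lo) & (f <= hi))[0]
    peaks = []
    for k in sel:
        if 0 < k < len(f) - 1 and y[k] > y[k - 1] and y[k] >= y[k + 1]:
            peaks.append(_quadratic_refine(f, y, k))
    peaks.sort(key=lambda p: -p[1])
    return peaks
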