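"""Laplace-domain stability of the dynamical modes.

Without noise, the self-consistent rate dynamics supports solutions
``exp(i omega' t)`` at every complex frequency ``omega'`` where an
eigenvalue of the analytically continued effective connectivity equals one,

    lambda_mode(omega') = 1,   omega' in C.

Writing ``omega' = Re(omega') + i Im(omega')``, the solution oscillates at
``Re(omega')/2pi`` Hz and decays at rate ``Im(omega')`` (1/s); a mode is
unstable when ``Im(omega') < 0`` (growing oscillation).  A trajectory
crossing the point 1 at a purely real frequency marks the Hopf bifurcation
between the asynchronous-irregular and synchronous-irregular regimes.

Both the delay filter and the transfer function are entire/analytic in
``omega`` and are evaluated directly at complex arguments; continuation is
validated against the real axis in the test suite.  Roots are found with a
damped Newton iteration on the two real components of
``lambda(omega') - 1``, Jacobian from central complex differences, started
from the real-axis closest approach (several candidate starts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .meanfield import StationaryState
from .modes import ModeDecomposition, closest_approach
from .network import NetworkModel, perturb_indegree
from .response import effective_connectivity_at

__all__ = [
    "CriticalPoint",
    "find_critical_frequency",
    "hopf_scan",
    "solve_lambda_eq_one",
]

logger = logging.getLogger(__name__)


@dataclass
class CriticalPoint:
    """A complex frequency where a mode's eigenvalue equals one."""

    mode: int
    omega_prime: complex
    stable: bool
    decay_rate: float  # Im(omega'), 1/s; negative = growing
    frequency: float  # Re(omega')/2pi, Hz
    residual: float
    converged: bool


def _mode_eigenvalue(
    model: NetworkModel, state: StationaryState, omega: complex, lam_ref: complex
) -> complex:
    """Eigenvalue of Md(omega) continuously connected to ``lam_ref``."""
    Md = effective_connectivity_at(model, state, omega)
    lam = np.linalg.eigvals(Md)
    return lam[int(np.argmin(np.abs(lam - lam_ref)))]


def solve_lambda_eq_one(
    lambda_fn,
    starts,
    tol: float = 1e-8,
    max_iter: int = 100,
    trust_radius: float | None = None,
    on_new_start=None,
) -> tuple[complex, float] | None:
    """Damped Newton solution of ``lambda_fn(omega) = 1`` over complex omega.

    ``lambda_fn`` maps a complex angular frequency to a complex eigenvalue
    (analytic).  The derivative is taken by central differences along the
    real direction, which equals the complex derivative for analytic
    functions.  A start is abandoned when the iterate wanders more than
    ``trust_radius`` (rad/s) from its starting point, which keeps the search
    attached to the resonance it was seeded from.  Returns
    ``(omega', residual)`` for the first converged start, or ``None``.
    """
    best = None
    for w_start in starts:
        if on_new_start is not None:
            on_new_start()
        w = complex(w_start)
        ok = False
        for _ in range(max_iter):
            g = lambda_fn(w) - 1.0
            if abs(g) < tol:
                ok = True
                break
            h = 1e-4 * max(abs(w), 1.0)
            dg = (lambda_fn(w + h) - lambda_fn(w - h)) / (2 * h)
            if dg == 0:
                break
            step = -g / dg
            max_step = 2 * np.pi * 20.0
            if abs(step) > max_step:
                step *= max_step / abs(step)
            w = w + step
            if trust_radius is not None and abs(w - w_start) > trust_radius:
                break
        if ok:
            resid = abs(lambda_fn(w) - 1.0)
            if best is None or resid < best[1]:
                best = (w, resid)
            break
    return best


def find_critical_frequency(
    model: NetworkModel,
    state: StationaryState,
    decomp: ModeDecomposition,
    mode: int,
    band: tuple[float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CriticalPoint:
    """Solve lambda_mode(omega') = 1 in the complex frequency plane.

    The search starts from the mode's real-axis closest approach to 1 (and a
    few nearby candidates), tracking the eigenvalue by continuity from the
    real-axis value.  Classification: ``Im(omega') > 0`` means the mode
    decays (stable).
    """
    f0, dist0, _ = closest_approach(decomp.lambdas[:, mode], decomp.grid, band)
    k0 = int(np.argmin(np.abs(decomp.grid.freqs - f0)))
    lam_ref = decomp.lambdas[k0, mode]
    w0 = 2 * np.pi * f0
    starts = [w0 + 0j, w0 + 0.2j * abs(w0), w0 - 0.2j * abs(w0)]
    if abs(w0) < 1e-6:
        scale = 2 * np.pi * 10.0
        starts = [0j, 1j * scale, -1j * scale, scale + 0j]

    tracker = {"lam": lam_ref}

    def lam_fn(w: complex) -> complex:
        lam = _mode_eigenvalue(model, state, w, tracker["lam"])
        tracker["lam"] = lam
        return lam

    def reset():
        tracker["lam"] = lam_ref

    best = solve_lambda_eq_one(
        lam_fn,
        starts,
        tol=tol,
        max_iter=max_iter,
        trust_radius=2 * np.pi * 150.0,
        on_new_start=reset,
    )
    if best is None:
        logger.warning("find_critical_frequency: no convergence for mode %d", mode)
        return CriticalPoint(
            mode=mode,
            omega_prime=complex(np.nan, np.nan),
            stable=True,
            decay_rate=np.nan,
            frequency=np.nan,
            residual=np.inf,
            converged=False,
        )
    w, resid = best
    # canonical representative with non-negative oscillation frequency
    if w.real < 0:
        w = -w.conjugate()
    return CriticalPoint(
        mode=mode,
        omega_prime=w,
        stable=w.imag > 0,
        decay_rate=w.imag,
        frequency=w.real / (2 * np.pi),
        residual=resid,
        converged=True,
    )


def hopf_scan(
    model: NetworkModel,
    state: StationaryState,
    target,
    source,
    alpha_range: tuple[float, float],
    mode: int,
    decomp: ModeDecomposition,
    band: tuple[float, float] | None = None,
    tol: float = 1e-4,
    max_bisect: int = 60,
) -> float | None:
    """Bisection for the perturbation strength at the stability boundary.

    Scales the indegree of one connection by ``(1+alpha)`` with the working
    point held fixed, and finds ``alpha*`` where ``Im(omega')`` of the
    tracked mode changes sign.  Returns ``None`` if the decay rate does not
    change sign over ``alpha_range``.
    """

    def decay(alpha: float) -> float:
        pert = perturb_indegree(model, target, source, alpha)
        cp = find_critical_frequency(pert, state, decomp, mode, band=band)
        if not cp.converged:
            raise RuntimeError(f"critical-frequency search failed at alpha={alpha}")
        return cp.decay_rate

    a, b = alpha_range
    da, db = decay(a), decay(b)
    if da == 0:
        return a
    if db == 0:
        return b
    if np.sign(da) == np.sign(db):
        logger.info("hopf_scan: no stability change in range %s", alpha_range)
        return None
    for _ in range(max_bisect):
        mid = 0.5 * (a + b)
        dm = decay(mid)
        if abs(b - a) < tol:
            return mid
        if np.sign(dm) == np.sign(da):
            a, da = mid, dm
        else:
            b, db = mid, dm
    return 0.5 * (a + b)
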