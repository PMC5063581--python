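"""Eigenmode decomposition, tracking, and mode-based spectrum reconstruction."""

import numpy as np
import pytest

from circuitspectra import FrequencyGrid, decompose, noise_matrix, p_factor
from circuitspectra.modes import closest_approach, mode_pair_spectra, mode_spectrum_approx
from circuitspectra.spectra import cross_spectra, propagator

from conftest import make_random_network
from test_spectra import _stub

from circuitspectra import CircuitAnalysis


def random_Md(seed, n=3, F=40):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    base *= 0.7 / max(abs(np.linalg.eigvals(base)))
    grid = FrequencyGrid(np.arange(0.0, float(F), 1.0))
    # smooth frequency dependence, spectral radius < 1 everywhere
    Md = np.array([base * np.exp(-0.01j * f) / (1 + 0.002 * f) for f in grid.freqs])
    return _stub(grid, Md)


def test_diagonal_matrix_trivial_decomposition():
    grid = FrequencyGrid(np.array([0.0, 1.0]))
    diag = np.array([0.5 + 0j, -0.2 + 0j, 0.1 + 0j])
    Md = _stub(grid, np.array([np.diag(diag)] * 2))
    dec = decompose(Md)
    assert np.allclose(np.sort_complex(dec.lambdas[0]), np.sort_complex(diag))
    # eigenvectors are (signed) unit vectors with v^T u = 1
    prod = np.einsum("ij,ij->j", dec.v[0], dec.u[0])
    assert np.allclose(prod, 1)


def test_reconstruction_and_biorthonormality(ei_analysis):
    dec = ei_analysis.modes
    Md = ei_analysis.Md.Md
    for k in (0, 7, 31):
        lam, u, v = dec.lambdas[k], dec.u[k], dec.v[k]
        rec = sum(lam[i] * np.outer(u[:, i], v[:, i]) for i in range(len(lam)))
        assert np.allclose(rec, Md[k], atol=1e-8)
        assert np.allclose(v.T @ u, np.eye(len(lam)), atol=1e-9)


def test_propagator_shares_eigenvectors(ei_analysis):
    dec = ei_analysis.modes
    P = propagator(ei_analysis.Md)
    for k in (3, 20):
        for i in range(dec.n_modes):
            u = dec.u[k][:, i]
            assert np.allclose(P[k] @ u, u / (1 - dec.lambdas[k, i]), atol=1e-8)


def test_tracking_continuity(micro_analysis):
    """Tracked trajectories move in small steps between neighbouring frequencies."""
    dec = micro_analysis.modes
    steps = np.abs(np.diff(dec.lambdas, axis=0))
    rel = steps / (1.0 + np.abs(dec.lambdas[:-1]))
    assert np.max(rel) < 0.05  # smooth on the 1 Hz grid


def test_trajectory_conjugate_symmetry(ei_analysis):
    """lambda(-omega) = conj(lambda(omega)) for each tracked mode."""
    from circuitspectra.response import effective_connectivity_at

    m, st = ei_analysis.model, ei_analysis.state
    w = 2 * np.pi * 36.0
    lp = np.sort_complex(np.linalg.eigvals(effective_connectivity_at(m, st, w)))
    lm = np.sort_complex(np.linalg.eigvals(effective_connectivity_at(m, st, -w)))
    assert np.allclose(np.sort_complex(np.conj(lm)), lp, atol=1e-10)


def test_tracking_permutation_stable():
    Md = random_Md(3)
    dec = decompose(Md)
    perm = [2, 0, 1]
    Md_p = _stub(Md.grid, Md.Md[:, perm][:, :, perm])
    dec_p = decompose(Md_p)
    # same eigenvalue trajectories up to relabeling of modes
    for i in range(3):
        dists = [np.max(np.abs(dec_p.lambdas[:, j] - dec.lambdas[:, i]))
                 for j in range(3)]
        assert min(dists) < 1e-10


def test_p_factor_values():
    assert p_factor(np.array([0.0 + 0j]))[0] == pytest.approx(1.0)
    assert p_factor(np.array([0.5 + 0j]))[0] == pytest.approx(2.0)
    p = p_factor(np.array([1.0 + 0j]))
    assert np.isinf(p[0])


def test_closest_approach_constant_zero():
    grid = FrequencyGrid(np.arange(0.0, 50.0, 1.0))
    lam = np.zeros(50, complex)
    f, d, side = closest_approach(lam, grid, band=(10.0, 30.0))
    assert d == pytest.approx(1.0)
    assert f == 10.0
    assert side == "left"


def test_mode_pair_sum_equals_full_spectrum():
    """Completeness: summing all mode pairs reproduces P D P^dagger."""
    for seed in (0, 1, 2):
        Md = random_Md(seed)
        D = np.diag(np.random.default_rng(seed).uniform(0.001, 0.01, 3))
        dec = decompose(Md)
        C_modes = mode_pair_spectra(dec, D)
        C_full = np.real(np.einsum("fii->fi", cross_spectra(Md, D)))
        assert np.allclose(C_modes, C_full, atol=1e-8)


def test_single_population_mode_approx_exact():
    """With one population there is one mode: the approximation is the spectrum."""
    from circuitspectra import NetworkModel, solve_selfconsistent
    from conftest import PD_PARAMS, W_UNIT

    m = NetworkModel(
        labels=["I"], sizes=[500.0], K=[[300.0]], W=[[-4 * W_UNIT]], g=4.0,
        d_mean=[[0.75e-3]], d_std=[[0.5e-3]], K_ext=[1400.0], r_ext=8.0,
        w_ext=W_UNIT, neuron=[PD_PARAMS],
    )
    ana = CircuitAnalysis(m, FrequencyGrid.default(300.0, 10.0))
    D = noise_matrix(ana.state, m.sizes)
    approx = mode_spectrum_approx(ana.modes, D, mode=0)
    assert np.allclose(approx, ana.spectra.C, rtol=1e-10)
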