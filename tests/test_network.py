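"""Fixture loading, indegree perturbation, compensation and isolation."""

import hashlib
from importlib import resources

import numpy as np
import pytest

from circuitspectra import (
    compensate_external,
    isolate_subcircuit,
    load_microcircuit,
    perturb_indegree,
    solve_selfconsistent,
    working_point,
)

# pins the transcribed parameter table; any edit to the fixture must be deliberate
FIXTURE_SHA256 = "150a66ff6ee5f7f2e6f3e48cf626db7847fc9cf55ae4a78d7826d407f865457f"


def test_fixture_checksum():
    data = resources.files("circuitspectra.data").joinpath("microcircuit.yaml").read_bytes()
    assert hashlib.sha256(data).hexdigest() == FIXTURE_SHA256


def test_microcircuit_modifications(microcircuit):
    m = microcircuit
    base = load_microcircuit(modified=False)
    assert m.labels == ["2/3E", "2/3I", "4E", "4I", "5E", "5I", "6E", "6I"]
    assert m.sizes.sum() == 77169
    assert all(p.tau_s == 0.5e-3 for p in m.neuron)
    assert np.all(m.d_std == 1e-3)
    i4E, i4I = m.index("4E"), m.index("4I")
    assert m.K[i4E, i4I] == pytest.approx(0.85 * base.K[i4E, i4I])
    assert m.K_ext[i4E] == pytest.approx(0.81 * base.K_ext[i4E])
    # only those three entries differ
    other = np.ones((8, 8), bool)
    other[i4E, i4I] = False
    assert np.array_equal(m.K[other], base.K[other])


def test_weight_sign_pattern(microcircuit):
    m = microcircuit
    inh = [j for j, lab in enumerate(m.labels) if lab.endswith("I")]
    exc = [j for j, lab in enumerate(m.labels) if lab.endswith("E")]
    assert np.all(m.W[:, inh] < 0)
    assert np.all(m.W[:, exc] > 0)
    assert np.allclose(m.W[:, inh], -m.g * m.w_ext)
    # doubled feed-forward weight 4E -> 2/3E
    assert m.W[m.index("2/3E"), m.index("4E")] == pytest.approx(2 * m.w_ext)


@pytest.mark.parametrize(
    "target,source,alpha,factor",
    [("4I", "4I", 0.10, 1.10), ("2/3E", "4E", 0.0, 1.0), ("5I", "5E", -0.15, 0.85)],
)
def test_perturb_indegree(microcircuit, target, source, alpha, factor):
    m = microcircuit
    pert = perturb_indegree(m, target, source, alpha)
    i, j = m.index(target), m.index(source)
    assert pert.K[i, j] == pytest.approx(factor * m.K[i, j])
    mask = np.ones((8, 8), bool)
    mask[i, j] = False
    assert np.array_equal(pert.K[mask], m.K[mask])
    # original untouched
    assert m.K[i, j] == pytest.approx(load_microcircuit().K[i, j])


def test_perturb_indegree_invalid(microcircuit):
    with pytest.raises(ValueError):
        perturb_indegree(microcircuit, "4I", "4I", -1.5)


def test_compensate_restores_mean(microcircuit, micro_state):
    m = microcircuit
    pert = perturb_indegree(m, "4I", "4I", 0.10)
    comp, resid = compensate_external(m, pert, rates=micro_state.rates)
    wp0 = working_point(m, micro_state.rates)
    wp1 = working_point(comp, micro_state.rates)
    assert np.allclose(wp1.mu, wp0.mu, rtol=1e-10)
    # variance is not matched by the single mean channel; residual reported
    i4I = m.index("4I")
    assert abs(resid[i4I]) > 0
    assert np.allclose(wp1.sigma**2 - wp0.sigma**2, resid, atol=1e-10)


def test_compensate_two_channel_exact(microcircuit, micro_state):
    m = microcircuit
    pert = perturb_indegree(m, "5I", "5E", -0.15)
    comp, resid = compensate_external(m, pert, rates=micro_state.rates, two_channel=True)
    assert np.allclose(resid, 0)
    wp0 = working_point(m, micro_state.rates)
    wp1 = working_point(comp, micro_state.rates)
    assert np.allclose(wp1.mu, wp0.mu, rtol=1e-10)
    assert np.allclose(wp1.sigma, wp0.sigma, rtol=1e-10)


def test_compensated_rates_unchanged(microcircuit, micro_state):
    """Perturb-and-compensate leaves the self-consistent rates at the originals."""
    pert = perturb_indegree(microcircuit, "4I", "4I", 0.10)
    comp, _ = compensate_external(
        microcircuit, pert, rates=micro_state.rates, two_channel=True
    )
    st = solve_selfconsistent(comp, init=micro_state.rates)
    assert st.converged
    assert np.allclose(st.rates, micro_state.rates, rtol=1e-6)


def test_isolate_preserves_working_point(microcircuit, micro_state):
    m = microcircuit
    iso = isolate_subcircuit(m, ["2/3E", "2/3I"], micro_state.rates)
    wp0 = working_point(m, micro_state.rates)
    wp1 = working_point(iso, micro_state.rates)
    assert np.allclose(wp1.mu, wp0.mu, rtol=1e-12)
    assert np.allclose(wp1.sigma, wp0.sigma, rtol=1e-12)
    keep = [m.index("2/3E"), m.index("2/3I")]
    mask = np.zeros((8, 8), bool)
    mask[np.ix_(keep, keep)] = True
    assert np.array_equal(iso.K[~mask], np.zeros((~mask).sum()))
    assert np.array_equal(iso.K[mask], m.K[mask])


def test_isolate_keep_all_is_identity(microcircuit, micro_state):
    iso = isolate_subcircuit(microcircuit, np.ones((8, 8), bool), micro_state.rates)
    assert np.array_equal(iso.K, microcircuit.K)
    assert np.allclose(iso.ext_mu_offset, 0)


def test_isolate_single_connection_removal(microcircuit, micro_state):
    """Everything kept except one connection (the 4I <- 2/3E link)."""
    mask = np.ones((8, 8), bool)
    mask[microcircuit.index("4I"), microcircuit.index("2/3E")] = False
    iso = isolate_subcircuit(microcircuit, mask, micro_state.rates)
    assert iso.K[microcircuit.index("4I"), microcircuit.index("2/3E")] == 0
    wp0 = working_point(microcircuit, micro_state.rates)
    wp1 = working_point(iso, micro_state.rates)
    assert np.allclose(wp1.mu, wp0.mu)
    assert np.allclose(wp1.sigma, wp0.sigma)
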