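"""Shared fixtures: toy circuits and the (expensive) microcircuit pipeline."""

import numpy as np
import pytest

from circuitspectra import (
    CircuitAnalysis,
    FrequencyGrid,
    NetworkModel,
    NeuronParams,
    load_microcircuit,
    solve_selfconsistent,
)

PD_PARAMS = NeuronParams(
    tau_m=0.01, tau_s=0.5e-3, tau_ref=2e-3, V_th=15.0, V_reset=0.0, C_m=250.0
)
W_UNIT = 87.8 * 0.5e-3 / (250.0 * 1e-3)  # mV per PSC of 87.8 pA


def make_ei_network(
    k_ee=200.0, k_ei=300.0, k_ie=400.0, k_ii=300.0, g=4.0,
    k_ext=(1300.0, 1100.0), d_std=0.5e-3,
) -> NetworkModel:
    """Small excitatory-inhibitory circuit in a stable, fluctuation-driven regime."""
    w = W_UNIT
    K = np.array([[k_ee, k_ei], [k_ie, k_ii]])
    W = np.array([[w, -g * w], [w, -g * w]])
    d = np.array([[1.5e-3, 0.75e-3], [1.5e-3, 0.75e-3]])
    return NetworkModel(
        labels=["E", "I"], sizes=[1000.0, 250.0], K=K, W=W, g=g,
        d_mean=d, d_std=np.full((2, 2), d_std), K_ext=list(k_ext), r_ext=8.0,
        w_ext=w, neuron=[PD_PARAMS, PD_PARAMS],
    )


def make_random_network(rng: np.random.Generator, n: int = 3) -> NetworkModel:
    """Random n-population circuit in the fluctuation-driven regime.

    One inhibitory population plus n-1 excitatory ones, with indegrees
    jittered around an inhibition-dominated template so that most draws
    settle at low, stable rates (the regime the theory describes); callers
    still filter on the solved rates.
    """
    is_inh = np.zeros(n, bool)
    is_inh[-1] = True
    w = W_UNIT
    base = np.where(is_inh[None, :], 320.0, 180.0)  # inhibition-dominated
    K = base * rng.uniform(0.5, 1.5, size=(n, n))
    W = np.where(is_inh[None, :], -4.0 * w, w) * np.ones((n, n))
    d = np.where(is_inh[None, :], 0.75e-3, 1.5e-3) * np.ones((n, n))
    return NetworkModel(
        labels=[f"X{i}" + ("I" if is_inh[i] else "E") for i in range(n)],
        sizes=rng.uniform(500, 2000, size=n).round(),
        K=K, W=W, g=4.0, d_mean=d, d_std=np.full((n, n), 0.5e-3),
        K_ext=rng.uniform(1150, 1400, size=n).round(), r_ext=8.0, w_ext=w,
        neuron=[PD_PARAMS] * n,
    )


@pytest.fixture(scope="session")
def ei_analysis():
    model = make_ei_network()
    return CircuitAnalysis(model, FrequencyGrid.default(500.0, 2.0))


@pytest.fixture(scope="session")
def microcircuit():
    return load_microcircuit()


@pytest.fixture(scope="session")
def micro_state(microcircuit):
    st = solve_selfconsistent(microcircuit)
    assert st.converged
    return st


@pytest.fixture(scope="session")
def micro_analysis(microcircuit, micro_state):
    ana = CircuitAnalysis(microcircuit, FrequencyGrid.default(400.0, 1.0), state=micro_state)
    return ana
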