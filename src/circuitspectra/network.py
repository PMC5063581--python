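"""Network descriptions: neuron parameters, connectivity, and perturbations.

A :class:`NetworkModel` bundles everything the mean-field and linear-response
machinery needs to know about a circuit of LIF populations: population sizes,
the indegree matrix ``K`` (average number of synapses a neuron of the target
population receives from each source population), the signed synaptic weight
matrix ``W`` (effective post-synaptic amplitude in mV), delay statistics, and
the external Poisson drive.

Internal unit conventions: seconds, millivolts, spikes per second.  Fixture
files use the units of the experimental literature (ms, pA) and are converted
on load.  The PSC amplitude ``a`` (pA) of an exponential synaptic current with
decay time ``tau_s`` deposits total charge ``a * tau_s`` on the membrane, so
the effective weight is ``w = a * tau_s / C_m`` (mV).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "NeuronParams",
    "NetworkModel",
    "load_microcircuit",
    "load_config",
    "perturb_indegree",
    "compensate_external",
    "isolate_subcircuit",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF neuron parameters (exponential synaptic currents).

    All times in seconds, potentials in mV relative to rest, capacitance
    in pF.
    """

    tau_m: float
    tau_s: float
    tau_ref: float
    V_th: float
    V_reset: float
    C_m: float

    def __post_init__(self):
        if min(self.tau_m, self.tau_s) <= 0 or self.tau_ref < 0:
            raise ValueError("time constants must be positive")
        if self.V_th <= self.V_reset:
            raise ValueError("V_th must exceed V_reset")


@dataclass
class NetworkModel:
    """An N-population circuit of LIF neurons with delayed connections.

    ``K[i, j]`` is the indegree from source population ``j`` to target
    population ``i`` (real-valued so fractional perturbations are exact);
    ``W[i, j]`` the signed effective weight in mV.  ``ext_mu_offset`` and
    ``ext_var_offset`` are additional external-input moments (mV, mV**2)
    representing auxiliary Poisson sources; they are used to keep working
    points fixed when connections are removed or compensated.
    """

    labels: list[str]
    sizes: np.ndarray
    K: np.ndarray
    W: np.ndarray
    g: float
    d_mean: np.ndarray
    d_std: np.ndarray
    K_ext: np.ndarray
    r_ext: float
    w_ext: float
    neuron: list[NeuronParams]
    ext_mu_offset: np.ndarray = field(default=None)
    ext_var_offset: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.labels)
        self.sizes = np.asarray(self.sizes, dtype=float)
        for name in ("K", "W", "d_mean", "d_std"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            setattr(self, name, arr)
        self.K_ext = np.asarray(self.K_ext, dtype=float)
        if self.ext_mu_offset is None:
            self.ext_mu_offset = np.zeros(n)
        if self.ext_var_offset is None:
            self.ext_var_offset = np.zeros(n)
        self.ext_mu_offset = np.asarray(self.ext_mu_offset, dtype=float)
        self.ext_var_offset = np.asarray(self.ext_var_offset, dtype=float)
        if np.any(self.K < 0):
            raise ValueError("indegrees must be non-negative")
        if np.any(self.d_std < 0):
            raise ValueError("delay standard deviations must be non-negative")

    @property
    def n_pop(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def copy(self, **changes) -> "NetworkModel":
        """Deep copy with selected fields replaced."""
        kwargs = {}
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if isinstance(val, np.ndarray):
                val = val.copy()
            elif isinstance(val, list):
                val = list(val)
            kwargs[f.name] = val
        kwargs.update(changes)
        return NetworkModel(**kwargs)

    # -- parameter arrays used throughout ---------------------------------
    def tau_m_arr(self) -> np.ndarray:
        return np.array([p.tau_m for p in self.neuron])

    def tau_s_arr(self) -> np.ndarray:
        return np.array([p.tau_s for p in self.neuron])


def _model_from_dict(cfg: dict) -> NetworkModel:
    labels = [str(x) for x in cfg["labels"]]
    n = len(labels)
    nrn = cfg["neuron"]
    params = NeuronParams(
        tau_m=nrn["tau_m_ms"] * 1e-3,
        tau_s=nrn["tau_s_ms"] * 1e-3,
        tau_ref=nrn["tau_ref_ms"] * 1e-3,
        V_th=nrn["V_th_mV"],
        V_reset=nrn["V_reset_mV"],
        C_m=nrn["C_m_pF"],
    )
    syn = cfg["synapse"]
    # pA * s / pF = mV
    w_e = syn["psc_amp_pA"] * params.tau_s / (params.C_m * 1e-3)
    g = float(syn["g"])
    # excitatory/inhibitory populations identified by label suffix
    is_inh = np.array([lab.endswith("I") for lab in labels])
    W = np.broadcast_to(np.where(is_inh[None, :], -g * w_e, w_e), (n, n)).copy()
    for spec in syn.get("weight_factors", []):
        W[labels.index(str(spec["target"])), labels.index(str(spec["source"]))] *= spec["factor"]
    dl = cfg["delays"]
    d_mean = np.where(is_inh[None, :], dl["mean_inh_ms"], dl["mean_exc_ms"]) * 1e-3
    d_mean = np.broadcast_to(d_mean, (n, n)).copy()
    d_std = dl["std_rel"] * d_mean
    ext = cfg["external"]
    return NetworkModel(
        labels=labels,
        sizes=np.asarray(cfg["sizes"], dtype=float),
        K=np.asarray(cfg["indegrees"], dtype=float),
        W=W,
        g=g,
        d_mean=d_mean,
        d_std=d_std,
        K_ext=np.asarray(ext["indegrees"], dtype=float),
        r_ext=float(ext["rate_per_s"]),
        w_ext=w_e,
        neuron=[params] * n,
    )


def load_config(path) -> NetworkModel:
    """Load a network description from a YAML config file."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return _model_from_dict(cfg)


def load_microcircuit(modified: bool = True) -> NetworkModel:
    """Load the bundled 8-population cortical microcircuit.

    With ``modified=True`` (default) the three stabilising modifications are
    applied to the base parameter set: the indegree from 4I to 4E is reduced
    by 15%, the delay standard deviation of every connection is set to 1 ms,
    and the external input to 4E is reduced by 19%.
    """
    try:
        src = resources.files("circuitspectra.data").joinpath("microcircuit.yaml")
        cfg = yaml.safe_load(src.read_text())
    except (FileNotFoundError, OSError) as err:
        raise FileNotFoundError(
            "bundled microcircuit fixture 'data/microcircuit.yaml' is missing "
            "or unreadable"
        ) from err
    for key in ("labels", "sizes", "indegrees", "neuron", "synapse", "delays", "external"):
        if key not in cfg:
            raise ValueError(f"microcircuit fixture is corrupt: missing section '{key}'")
    model = _model_from_dict(cfg)
    if modified:
        i4E, i4I = model.index("4E"), model.index("4I")
        model.K[i4E, i4I] *= 0.85
        model.d_std[:, :] = 1e-3
        model.K_ext[i4E] *= 0.81
    return model


def perturb_indegree(model: NetworkModel, target, source, alpha: float) -> NetworkModel:
    """Scale a single indegree ``K[target, source]`` by ``(1 + alpha)``.

    ``target``/``source`` may be population labels or indices.  The original
    model is left untouched.
    """
    if alpha < -1:
        raise ValueError("alpha < -1 would make the indegree negative")
    k = model.index(target) if isinstance(target, str) else int(target)
    l = model.index(source) if isinstance(source, str) else int(source)
    out = model.copy()
    out.K[k, l] *= 1.0 + alpha
    return out


def compensate_external(
    model_orig: NetworkModel,
    model_pert: NetworkModel,
    rates: np.ndarray | None = None,
    two_channel: bool = False,
) -> tuple[NetworkModel, np.ndarray]:
    """Adjust external drive of ``model_pert`` to restore the working point.

    The stationary rates of the original model (computed if not supplied) are
    frozen, and the change in recurrent mean input caused by the indegree
    perturbation is counteracted through the external Poisson channel
    (``K_ext``).  With a single channel the mean is restored exactly and the
    residual mismatch of the input variance is returned (mV^2, one value per
    population).  With ``two_channel=True`` an auxiliary external source
    absorbs the variance mismatch as well, so both moments are restored.
    """
    if model_orig.labels != model_pert.labels:
        raise ValueError("models must describe the same populations")
    if rates is None:
        from .meanfield import solve_selfconsistent

        rates = solve_selfconsistent(model_orig).rates
    rates = np.asarray(rates, dtype=float)
    tau_m = model_orig.tau_m_arr()
    dK = model_pert.K - model_orig.K
    # moment changes caused by the perturbed recurrent indegrees
    dmu = tau_m * ((dK * model_orig.W) @ rates)
    dvar = tau_m * ((dK * model_orig.W**2) @ rates)
    out = model_pert.copy()
    # mean channel: one external Poisson connection contributes
    # tau_m * w_ext * r_ext to mu
    unit = tau_m * out.w_ext * out.r_ext
    dK_ext = -dmu / unit
    new_K_ext = out.K_ext + dK_ext
    if np.any(new_K_ext < 0):
        bad = [out.labels[i] for i in np.where(new_K_ext < 0)[0]]
        raise ValueError(
            f"compensation would require negative external indegree for {bad}"
        )
    out.K_ext = new_K_ext
    # variance accounting: the mean-channel adjustment also changes sigma^2
    sigma_resid = dvar + dK_ext * tau_m * out.w_ext**2 * out.r_ext
    if two_channel:
        out.ext_var_offset = out.ext_var_offset - sigma_resid
        sigma_resid = np.zeros_like(sigma_resid)
    return out, sigma_resid


def isolate_subcircuit(
    model: NetworkModel,
    keep,
    rates: np.ndarray,
) -> NetworkModel:
    """Zero all connections outside ``keep``; preserve every working point.

    ``keep`` is either a boolean N x N mask, an iterable of
    ``(target, source)`` pairs (labels or indices), or an iterable of
    population labels (keeping all connections among them).  For each removed
    connection, its mean and variance contribution at the supplied
    full-circuit rates is transferred to the external drive, so both moments
    of every population's input are unchanged.
    """
    n = model.n_pop
    mask = np.zeros((n, n), dtype=bool)
    keep_arr = np.asarray(keep) if not isinstance(keep, (set, frozenset)) else None
    if keep_arr is not None and keep_arr.dtype == bool and keep_arr.shape == (n, n):
        mask = keep_arr.copy()
    else:
        items = list(keep)
        if items and not isinstance(items[0], (tuple, list)):
            # population subset: keep connections among them
            idx = [model.index(x) if isinstance(x, str) else int(x) for x in items]
            for i in idx:
                for j in idx:
                    mask[i, j] = True
        else:
            for t, s in items:
                i = model.index(t) if isinstance(t, str) else int(t)
                j = model.index(s) if isinstance(s, str) else int(s)
                mask[i, j] = True
    rates = np.asarray(rates, dtype=float)
    tau_m = model.tau_m_arr()
    removed = ~mask
    K_rm = np.where(removed, model.K, 0.0)
    dmu = tau_m * ((K_rm * model.W) @ rates)
    dvar = tau_m * ((K_rm * model.W**2) @ rates)
    out = model.copy()
    out.K = np.where(mask, model.K, 0.0)
    out.ext_mu_offset = out.ext_mu_offset + dmu
    out.ext_var_offset = out.ext_var_offset + dvar
    return out
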