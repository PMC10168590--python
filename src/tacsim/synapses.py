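"""Delayed, kernel-filtered synaptic transmission.

Each presynaptic spike, after an axonal delay ``t_d``, evokes a conductance
transient shaped by a double-exponential kernel

    S(s) = ( exp(-s/tau_d) - exp(-s/tau_r) ) / K,        s >= 0,

peak-normalised so that ``max_s S(s) = 1`` and the synaptic weight ``g`` is
the peak conductance.  The total drive onto neuron ``i`` is, in conductance
mode (population networks),

    I_syn,i(t) = sum_j g_ij S_ij(t - t_sp,j - t_d,ij) (E_syn,j - v_i),

so AMPA synapses (E_syn = 0 mV) depolarise and GABA_a synapses
(E_syn = -85 mV) hyperpolarise a neuron below/above reversal.  The two-neuron
motif instead uses a current-based form where ``g`` (mV) multiplies the
kernel directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynapseParams",
    "SynapseTable",
    "AMPA",
    "GABA_A",
    "synaptic_kernel",
    "kernel_peak_time",
    "kernel_norm",
    "total_synaptic_drive",
]


@dataclass(frozen=True)
class SynapseParams:
    """Kernel constants of one receptor class."""

    tau_r: float = 0.5
    tau_d: float = 3.0
    e_syn: float = 0.0
    t_d: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.tau_r < self.tau_d:
            raise ValueError(
                f"require 0 < tau_r < tau_d, got tau_r={self.tau_r}, tau_d={self.tau_d}"
            )
        if self.t_d < 0:
            raise ValueError("axonal delay must be non-negative")


#: AMPA-like excitatory receptor (Table values of the population model).
AMPA = SynapseParams(tau_r=0.5, tau_d=3.0, e_syn=0.0)
#: GABA_a-like inhibitory receptor.
GABA_A = SynapseParams(tau_r=0.5, tau_d=5.0, e_syn=-85.0)


def kernel_peak_time(params: SynapseParams) -> float:
    """Time of the kernel maximum: (tau_r tau_d/(tau_d - tau_r)) ln(tau_d/tau_r)."""
    return (
        params.tau_r * params.tau_d / (params.tau_d - params.tau_r)
    ) * math.log(params.tau_d / params.tau_r)


def kernel_norm(params: SynapseParams) -> float:
    """Peak value of the unnormalised double exponential."""
    s = kernel_peak_time(params)
    return math.exp(-s / params.tau_d) - math.exp(-s / params.tau_r)


def synaptic_kernel(s: float | np.ndarray, params: SynapseParams) -> float | np.ndarray:
    """Peak-normalised double-exponential activation at time ``s`` since arrival.

    Zero for ``s < 0`` (causality); maximum value 1 at ``kernel_peak_time``.
    """
    sv = np.asarray(s, dtype=float)
    k = (np.exp(-sv / params.tau_d) - np.exp(-sv / params.tau_r)) / kernel_norm(params)
    out = np.where(sv >= 0, k, 0.0)
    return float(out) if np.ndim(s) == 0 else out


@dataclass
class SynapseTable:
    """Sparse directed connections as parallel arrays.

    ``receptor[k]`` indexes into ``receptor_params`` (by convention 0 = AMPA /
    excitatory presynapse, 1 = GABA_a / inhibitory presynapse).  ``g0`` is the
    per-synapse baseline weight defining the soft-bound scales ``g_min`` and
    ``g_max`` of the plasticity rule.  ``conductance_mode`` selects the
    conductance form (population networks) versus the current-based form
    (two-neuron motif, weights in mV).
    """

    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    delay: np.ndarray
    receptor: np.ndarray
    plastic: np.ndarray
    g0: np.ndarray
    cell_type_pre: np.ndarray
    cell_type_post: np.ndarray
    receptor_params: tuple[SynapseParams, ...] = (AMPA, GABA_A)
    conductance_mode: bool = True
    g_min_factor: float = 0.01
    g_max_factor: float = 2.0

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        self.delay = np.asarray(self.delay, dtype=np.float64)
        self.receptor = np.asarray(self.receptor, dtype=np.int64)
        self.plastic = np.asarray(self.plastic, dtype=bool)
        self.g0 = np.asarray(self.g0, dtype=np.float64)
        n = len(self.pre)
        for name in ("post", "weight", "delay", "receptor", "plastic", "g0",
                     "cell_type_pre", "cell_type_post"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")
        if np.any(self.pre == self.post):
            raise ValueError("self-connections are not allowed")
        if np.any(self.delay < 0):
            raise ValueError("delays must be non-negative")

    def __len__(self) -> int:
        return len(self.pre)

    @property
    def g_min(self) -> np.ndarray:
        return self.g_min_factor * self.g0

    @property
    def g_max(self) -> np.ndarray:
        return self.g_max_factor * self.g0

    def params_of(self, k: int) -> SynapseParams:
        return self.receptor_params[int(self.receptor[k])]


def total_synaptic_drive(
    i: int,
    t: float,
    spikes,
    table: SynapseTable,
    v_i: float,
    cutoff_factor: float = 10.0,
) -> float:
    """Synaptic input current (mV) onto neuron ``i`` at time ``t`` (ms).

    Direct summation over the spike history -- the quadratic-cost oracle used
    to validate the engine's exponential accumulators.  Kernel evaluation is
    truncated at ``cutoff_factor * tau_d`` after arrival, which perturbs the
    drive by < 1e-6 of its peak for the default factor.
    """
    if i < 0 or i >= spikes.n_neurons:
        raise KeyError(f"unknown neuron id {i}")
    drive = 0.0
    incoming = np.flatnonzero(table.post == i)
    for k in incoming:
        params = table.params_of(k)
        pre_times = spikes.train(int(table.pre[k]))
        s = t - pre_times - table.delay[k]
        s = s[(s >= 0) & (s <= cutoff_factor * params.tau_d)]
        if s.size == 0:
            continue
        act = float(np.sum(synaptic_kernel(s, params)))
        if table.conductance_mode:
            drive += table.weight[k] * act * (params.e_syn - v_i)
        else:
            drive += table.weight[k] * act
    return drive
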