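"""Soft-bound symmetric Hebbian spike-timing-dependent plasticity.

For a pre/post spike-time difference ``dT = t_post - t_pre`` the weight change
is

    dT > 0:  dg = +A_plus  g_0 (1 - g/g_max) exp(-dT/gamma_plus)     (potentiation)
    dT < 0:  dg = -A_minus g_0 (g/g_0)       exp(+dT/gamma_minus)    (depression)
    dT = 0:  dg = 0,

with weight-dependent rates that vanish towards the bounds (soft-bound
regime).  The learning rates ``A_±`` are fractional: they scale the baseline
weight ``g_0``, so one isolated causal pairing at ``dT -> 0+`` moves a
mid-range weight by ``A_plus/2`` of its baseline regardless of the absolute
weight units (mV kicks in the two-neuron motif, dimensionless conductances in
the population networks).  Weights are additionally clipped into
``[g_min, g_max]``.  Defaults follow the study: ``A_plus = 2 A_minus = 0.02``,
``gamma_± = 10 ms``, ``g_min = 0.01 g_0``, ``g_max = 2 g_0``.

Pairing is all-to-all: every pre spike interacts with every post spike.  The
online implementation uses per-neuron exponential traces, which makes each
spike event O(fan-in + fan-out) while summing exactly the same pairwise terms.

``predicted_mean_change`` is the histogram-weighted mean of the (weight-free)
rule -- the study's independent predictor of the direction of plasticity from
a measured spike-timing-difference distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "STDPParams",
    "DeltaTHistogram",
    "stdp_delta",
    "clip_weight",
    "OnlineSTDP",
    "predicted_mean_change",
    "stdp_fixed_point",
]


@dataclass(frozen=True)
class STDPParams:
    a_plus: float = 0.02
    a_minus: float = 0.01
    gamma_plus: float = 10.0
    gamma_minus: float = 10.0
    g_0: float = 1.0
    g_min_factor: float = 0.01
    g_max_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.a_plus <= 0 or self.a_minus <= 0:
            raise ValueError("learning rates must be positive")
        if not self.g_min_factor < 1.0 < self.g_max_factor:
            raise ValueError("require g_min < g_0 < g_max")

    @property
    def g_min(self) -> float:
        return self.g_min_factor * self.g_0

    @property
    def g_max(self) -> float:
        return self.g_max_factor * self.g_0


def stdp_delta(g: float, delta_t: float, params: STDPParams) -> float:
    """Weight change for one pre/post pairing with time difference ``delta_t``."""
    if delta_t > 0:
        return params.a_plus * params.g_0 * (1.0 - g / params.g_max) * math.exp(
            -delta_t / params.gamma_plus
        )
    if delta_t < 0:
        return -params.a_minus * g * math.exp(delta_t / params.gamma_minus)
    return 0.0


def clip_weight(g: float | np.ndarray, params: STDPParams) -> float | np.ndarray:
    """Clamp ``g`` into the hard bounds [g_min, g_max]."""
    return np.clip(g, params.g_min, params.g_max)


class OnlineSTDP:
    """Event-driven all-to-all STDP via per-neuron exponential traces.

    ``trace_pre[j]`` carries ``sum exp(-(t - t_s)/gamma_plus)`` over past
    spikes of neuron ``j`` and drives potentiation of j's outgoing synapses
    whenever their postsynaptic neuron fires; ``trace_post`` symmetrically
    drives depression.  Within one event batch (identical timestamps)
    potentiation is applied before depression and coincident pairs
    (``dT = 0``) contribute nothing, because traces are updated only after
    both passes.  Weight updates are applied sequentially and clipped
    per event (``clip=True``) or left unclipped for oracle comparison.

    Reference implementation operating on a :class:`~tacsim.synapses.SynapseTable`;
    the network engine inlines the identical scheme.
    """

    def __init__(self, table, params: STDPParams, n_neurons: int, clip: bool = True):
        self.table = table
        self.params = params
        self.clip = clip
        self.trace_pre = np.zeros(n_neurons)
        self.trace_post = np.zeros(n_neurons)
        self._t_last = 0.0
        self._out = [np.flatnonzero(table.pre == i) for i in range(n_neurons)]
        self._in = [np.flatnonzero(table.post == i) for i in range(n_neurons)]
        self._gmin = np.asarray(table.g_min, dtype=float)
        self._gmax = np.asarray(table.g_max, dtype=float)

    def _decay_to(self, t: float) -> None:
        dt = t - self._t_last
        if dt < 0:
            raise ValueError("events must be processed in time order")
        if dt > 0:
            self.trace_pre *= math.exp(-dt / self.params.gamma_plus)
            self.trace_post *= math.exp(-dt / self.params.gamma_minus)
            self._t_last = t

    def process(self, neurons, t: float) -> None:
        """Apply the rule for neurons spiking simultaneously at time ``t`` (ms)."""
        neurons = np.atleast_1d(np.asarray(neurons, dtype=np.int64))
        self._decay_to(t)
        tab = self.table
        p = self.params
        # Potentiation: each spiker acts as postsynaptic partner.
        for i in neurons:
            for k in self._in[int(i)]:
                if not tab.plastic[k]:
                    continue
                dg = p.a_plus * tab.g0[k] * (
                    1.0 - tab.weight[k] / self._gmax[k]
                ) * self.trace_pre[tab.pre[k]]
                tab.weight[k] += dg
                if self.clip:
                    tab.weight[k] = min(max(tab.weight[k], self._gmin[k]), self._gmax[k])
        # Depression: each spiker acts as presynaptic partner.
        for i in neurons:
            for k in self._out[int(i)]:
                if not tab.plastic[k]:
                    continue
                dg = p.a_minus * tab.weight[k] * self.trace_post[tab.post[k]]
                tab.weight[k] -= dg
                if self.clip:
                    tab.weight[k] = min(max(tab.weight[k], self._gmin[k]), self._gmax[k])
        for i in neurons:
            self.trace_pre[int(i)] += 1.0
            self.trace_post[int(i)] += 1.0


@dataclass
class DeltaTHistogram:
    """Normalised distribution f(dT) of pre/post spike-timing differences.

    ``edges`` (ms) has one more entry than ``density``; the density integrates
    to one over the pairing window [-window, window].
    """

    edges: np.ndarray
    density: np.ndarray
    window: float

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if len(self.edges) != len(self.density) + 1:
            raise ValueError("edges must have len(density) + 1 entries")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def mass(self) -> float:
        return float(np.sum(self.density * np.diff(self.edges)))


def predicted_mean_change(
    hist: DeltaTHistogram,
    params: STDPParams,
    g: float | None = None,
) -> float:
    """Mean weight change per pairing event predicted from f(dT).

    Integrates the STDP kernel against the histogram:
    ``-A_minus exp(dT/gamma_minus)`` over dT < 0 and
    ``+A_plus exp(-dT/gamma_plus)`` over dT > 0 (the depression branch keeps
    the negative sign of the learning rule, so left-shifted distributions
    predict depression).  A positive return value predicts potentiation.

    With ``g=None`` the bare amplitudes ``A_±`` are used (the weight-free
    printed form of the predictor).  Because ``A_plus = 2 A_minus`` by
    default, that form carries a potentiation bias even for a flat f(dT); the
    rule's *effective* rates are the weight-dependent factors
    ``A_plus (1 - g/g_max)`` and ``A_minus (g/g_0)``, which balance exactly at
    the baseline weight.  Passing an operating-point weight ``g`` (typically
    ``params.g_0``) evaluates the kernel at those effective rates; this is
    the variant whose sign tracks simulated weight changes.
    """
    if abs(hist.mass - 1.0) > 1e-6:
        raise ValueError("histogram must be normalised to unit mass")
    if g is None:
        a_p, a_m = params.a_plus, params.a_minus
    else:
        a_p = params.a_plus * (1.0 - g / params.g_max)
        a_m = params.a_minus * (g / params.g_0)
    c = hist.centers
    widths = np.diff(hist.edges)
    kern = np.where(
        c > 0,
        a_p * np.exp(-c / params.gamma_plus),
        np.where(c < 0, -a_m * np.exp(c / params.gamma_minus), 0.0),
    )
    return float(np.sum(kern * hist.density * widths))


def stdp_fixed_point(params: STDPParams) -> float:
    """Weight g* where potentiation and depression rates balance under flat f(dT).

    Solves ``A_plus (1 - g/g_max) gamma_plus = A_minus (g/g_0) gamma_minus``.
    With the study defaults (A_plus = 2 A_minus, gamma_plus = gamma_minus,
    g_max = 2 g_0) the fixed point is exactly g_0, which is why sham weights
    fluctuate about their baseline.
    """
    num = params.a_plus * params.gamma_plus
    den = params.a_minus * params.gamma_minus / params.g_0 + params.a_plus * params.gamma_plus / params.g_max
    return num / den
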