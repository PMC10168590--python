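"""Construction of the three study networks.

* ``build_pair_motif`` -- two mutually synapsing excitatory LIF neurons with
  current-based plastic synapses (the minimal timescale-heterogeneity motif);
* ``build_cortical_layer`` -- one balanced cortical layer: 4:1 excitatory to
  inhibitory ratio, uniform connection probability 0.1, conductance synapses,
  heterogeneous membrane time constants;
* ``build_multilayer`` -- four such layers (III, IV, V, VI) with layer-specific
  MTC distributions, inter-laminar excitatory wiring at probability 0.05 on a
  configurable adjacency, and no inter-laminar inhibitory connections.

All wiring is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .synapses import AMPA, GABA_A, SynapseParams, SynapseTable
from .synthetic_inputs import (
    LayerProfile,
    MTCDistributionSpec,
    initial_weights,
    layer_profiles,
    sample_delays,
    sample_mtc,
)

__all__ = [
    "NeuronArray",
    "NetworkSpec",
    "LaminarAdjacency",
    "LayerConfig",
    "build_pair_motif",
    "build_cortical_layer",
    "build_multilayer",
    "empty_synapse_table",
]

LAYER_LABELS = ("III", "IV", "V", "VI")

#: baseline weights of the population model, by (pre cell type) in {E, I}
G0_E = 5e-5
G0_I = 25e-5


@dataclass
class NeuronArray:
    """Per-neuron biophysics of a network (cell_type: 0 = E, 1 = I)."""

    tau_m: np.ndarray
    v_rest: np.ndarray
    cell_type: np.ndarray
    layer: np.ndarray
    rheobase_offset: np.ndarray
    v_thr: float = -54.0
    tau_ref: float = 2.0

    def __post_init__(self) -> None:
        self.tau_m = np.asarray(self.tau_m, float)
        self.v_rest = np.asarray(self.v_rest, float)
        self.cell_type = np.asarray(self.cell_type, np.int64)
        self.layer = np.asarray(self.layer, np.int64)
        self.rheobase_offset = np.asarray(self.rheobase_offset, float)
        if not (len(self.tau_m) == len(self.v_rest) == len(self.cell_type)
                == len(self.layer) == len(self.rheobase_offset)):
            raise ValueError("neuron columns must have equal length")
        if np.any(self.tau_m <= 0):
            raise ValueError("tau_m must be positive")

    @property
    def n(self) -> int:
        return len(self.tau_m)

    @property
    def excitatory(self) -> np.ndarray:
        return self.cell_type == 0

    @property
    def inhibitory(self) -> np.ndarray:
        return self.cell_type == 1


@dataclass
class NetworkSpec:
    """A wired network: neurons + synapse table + build metadata."""

    neurons: NeuronArray
    synapses: SynapseTable
    metadata: dict


@dataclass(frozen=True)
class LaminarAdjacency:
    """Directed allowed inter-laminar E->E projections over the four layers.

    ``allowed[(src, dst)]`` for distinct layer labels; the diagonal is handled
    by the intra-laminar wiring, never by this matrix.  The default enables
    every ordered pair, which is fully overridable in configuration.
    """

    allowed: tuple[tuple[str, str], ...] = tuple(
        (a, b) for a in LAYER_LABELS for b in LAYER_LABELS if a != b
    )
    p: float = 0.05

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.allowed

    @staticmethod
    def none() -> "LaminarAdjacency":
        return LaminarAdjacency(allowed=())


@dataclass(frozen=True)
class LayerConfig:
    """Size, wiring and input statistics of one balanced layer."""

    n_total: int = 2000
    ei_ratio: int = 4
    p_connect: float = 0.1
    mtc: MTCDistributionSpec = MTCDistributionSpec(mean=10.0, sd=3.0)
    v_rest_mean: float = -60.0
    v_rest_jitter: float = 0.2
    g0_e: float = G0_E
    g0_i: float = G0_I
    sigma_g_factor: float = 0.1
    delay_range: tuple[float, float] = (0.5, 1.0)
    rheobase_offset: float = 0.0


def empty_synapse_table() -> SynapseTable:
    z = np.zeros(0)
    return SynapseTable(
        pre=z, post=z, weight=z, delay=z, receptor=z, plastic=np.zeros(0, bool),
        g0=z, cell_type_pre=z.astype(np.int64), cell_type_post=z.astype(np.int64),
    )


def _plastic_flags(ct_pre: np.ndarray, ct_post: np.ndarray) -> np.ndarray:
    """E->E, E->I and I->E synapses are plastic; I->I stays static."""
    return ~((ct_pre == 1) & (ct_post == 1))


def build_pair_motif(
    tau_1: float,
    tau_2: float,
    g_0: float = 0.1,
    delay: float = 0.5,
    kernel: SynapseParams = SynapseParams(tau_r=0.5, tau_d=3.0, e_syn=0.0, t_d=0.5),
    v_rest: float = -60.0,
    v_thr: float = -54.0,
    tau_ref: float = 2.0,
) -> NetworkSpec:
    """Two mutually coupled excitatory neurons with current-based synapses.

    Weights are in mV (the kernel peak adds ``g`` mV of drive); both synapses
    are plastic with baseline ``g_0 = 0.1`` mV and a fixed 0.5 ms delay.
    """
    if tau_1 <= 0 or tau_2 <= 0:
        raise ValueError("time constants must be positive")
    neurons = NeuronArray(
        tau_m=np.array([tau_1, tau_2]),
        v_rest=np.full(2, v_rest),
        cell_type=np.zeros(2, np.int64),
        layer=np.full(2, -1, np.int64),
        rheobase_offset=np.zeros(2),
        v_thr=v_thr,
        tau_ref=tau_ref,
    )
    table = SynapseTable(
        pre=np.array([0, 1]),
        post=np.array([1, 0]),
        weight=np.full(2, g_0),
        delay=np.full(2, delay),
        receptor=np.zeros(2, np.int64),
        plastic=np.ones(2, bool),
        g0=np.full(2, g_0),
        cell_type_pre=np.zeros(2, np.int64),
        cell_type_post=np.zeros(2, np.int64),
        receptor_params=(kernel, GABA_A),
        conductance_mode=False,
    )
    return NetworkSpec(
        neurons=neurons,
        synapses=table,
        metadata={"kind": "pair", "tau": (tau_1, tau_2), "g_0": g_0},
    )


def _random_edges(
    pre_pool: np.ndarray,
    post_pool: np.ndarray,
    p: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli(p) directed edges between two index pools, no self-loops."""
    n_pre, n_post = len(pre_pool), len(post_pool)
    # sample per pre neuron to bound memory at n_post per draw
    pres, posts = [], []
    for a in pre_pool:
        mask = rng.random(n_post) < p
        targets = post_pool[mask]
        targets = targets[targets != a]
        if targets.size:
            pres.append(np.full(targets.size, a, np.int64))
            posts.append(targets.astype(np.int64))
    if not pres:
        return np.zeros(0, np.int64), np.zeros(0, np.int64)
    return np.concatenate(pres), np.concatenate(posts)


def _wire_population(
    neurons: NeuronArray,
    idx: np.ndarray,
    cfg: LayerConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Intra-population Bernoulli wiring with per-presynaptic-type baselines."""
    ct = neurons.cell_type
    e_idx = idx[ct[idx] == 0]
    i_idx = idx[ct[idx] == 1]
    cols: dict[str, list[np.ndarray]] = {k: [] for k in
                                         ("pre", "post", "weight", "delay", "receptor", "g0")}
    for pre_pool, g0, receptor in ((e_idx, cfg.g0_e, 0), (i_idx, cfg.g0_i, 1)):
        pres, posts = _random_edges(pre_pool, idx, cfg.p_connect, rng)
        w = initial_weights(pres.size, g0, cfg.sigma_g_factor * g0, rng)
        d = sample_delays(pres.size, *cfg.delay_range, rng)
        cols["pre"].append(pres)
        cols["post"].append(posts)
        cols["weight"].append(w)
        cols["delay"].append(d)
        cols["receptor"].append(np.full(pres.size, receptor, np.int64))
        cols["g0"].append(np.full(pres.size, g0))
    return {k: np.concatenate(v) for k, v in cols.items()}


def build_cortical_layer(
    config: LayerConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> NetworkSpec:
    """One balanced excitatory/inhibitory layer in the asynchronous regime.

    ``n_total`` splits 4:1 into E and I; every ordered cell-type pair is wired
    with probability ``p_connect``; per-neuron MTCs come from the configured
    distribution and resting potentials carry a small uniform jitter reused as
    the reset value.
    """
    cfg = config or LayerConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    if cfg.n_total % (cfg.ei_ratio + 1):
        raise ValueError(f"n_total must split {cfg.ei_ratio}:1 exactly")
    n_i = cfg.n_total // (cfg.ei_ratio + 1)
    n_e = cfg.n_total - n_i
    ct = np.concatenate([np.zeros(n_e, np.int64), np.ones(n_i, np.int64)])
    neurons = NeuronArray(
        tau_m=sample_mtc(cfg.mtc, cfg.n_total, rng),
        v_rest=cfg.v_rest_mean + rng.uniform(-cfg.v_rest_jitter, cfg.v_rest_jitter, cfg.n_total),
        cell_type=ct,
        layer=np.zeros(cfg.n_total, np.int64),
        rheobase_offset=np.full(cfg.n_total, cfg.rheobase_offset),
    )
    idx = np.arange(cfg.n_total)
    cols = _wire_population(neurons, idx, cfg, rng)
    table = SynapseTable(
        pre=cols["pre"],
        post=cols["post"],
        weight=cols["weight"],
        delay=cols["delay"],
        receptor=cols["receptor"],
        plastic=_plastic_flags(ct[cols["pre"]], ct[cols["post"]]),
        g0=cols["g0"],
        cell_type_pre=ct[cols["pre"]],
        cell_type_post=ct[cols["post"]],
        receptor_params=(AMPA, GABA_A),
        conductance_mode=True,
    )
    return NetworkSpec(
        neurons=neurons,
        synapses=table,
        metadata={
            "kind": "layer",
            "n_e": n_e,
            "n_i": n_i,
            "p": cfg.p_connect,
            "seed": seed,
        },
    )


def build_multilayer(
    layer_size: int = 600,
    profiles: Sequence[LayerProfile] | None = None,
    adjacency: LaminarAdjacency | None = None,
    layer_config: LayerConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> NetworkSpec:
    """Four-layer laminar network with layer-specific timescales.

    Each layer is an independently wired balanced population of
    ``layer_size`` neurons (4:1 split, intra-laminar probability 0.1).
    Inter-laminar wiring connects excitatory neurons of allowed ordered layer
    pairs with probability ``adjacency.p`` (default 0.05); inhibitory neurons
    never project across layers.  Per-layer rheobase offsets from the
    profiles equalise baseline excitability across timescale statistics.
    """
    profiles = list(profiles) if profiles is not None else layer_profiles()
    if len(profiles) != 4:
        raise ValueError("exactly four layer profiles required")
    adjacency = adjacency or LaminarAdjacency()
    base = layer_config or LayerConfig()
    if rng is None:
        rng = np.random.default_rng(seed)

    parts = []
    offset = 0
    for li, prof in enumerate(profiles):
        cfg = replace(base, n_total=layer_size, mtc=prof.mtc,
                      rheobase_offset=prof.rheobase_offset)
        sub = build_cortical_layer(cfg, rng=rng)
        sub.neurons.layer[:] = li
        sub.synapses.pre += offset
        sub.synapses.post += offset
        parts.append(sub)
        offset += layer_size

    neurons = NeuronArray(
        tau_m=np.concatenate([p.neurons.tau_m for p in parts]),
        v_rest=np.concatenate([p.neurons.v_rest for p in parts]),
        cell_type=np.concatenate([p.neurons.cell_type for p in parts]),
        layer=np.concatenate([p.neurons.layer for p in parts]),
        rheobase_offset=np.concatenate([p.neurons.rheobase_offset for p in parts]),
    )
    cols = {
        "pre": [p.synapses.pre for p in parts],
        "post": [p.synapses.post for p in parts],
        "weight": [p.synapses.weight for p in parts],
        "delay": [p.synapses.delay for p in parts],
        "receptor": [p.synapses.receptor for p in parts],
        "g0": [p.synapses.g0 for p in parts],
    }
    labels = [p.label for p in profiles]
    for si, src in enumerate(labels):
        for di, dst in enumerate(labels):
            if si == di or (src, dst) not in adjacency:
                continue
            src_e = np.flatnonzero((neurons.layer == si) & neurons.excitatory)
            dst_e = np.flatnonzero((neurons.layer == di) & neurons.excitatory)
            pres, posts = _random_edges(src_e, dst_e, adjacency.p, rng)
            cols["pre"].append(pres)
            cols["post"].append(posts)
            cols["weight"].append(
                initial_weights(pres.size, base.g0_e, base.sigma_g_factor * base.g0_e, rng)
            )
            cols["delay"].append(sample_delays(pres.size, *base.delay_range, rng))
            cols["receptor"].append(np.zeros(pres.size, np.int64))
            cols["g0"].append(np.full(pres.size, base.g0_e))
    cat = {k: np.concatenate(v) for k, v in cols.items()}
    ct = neurons.cell_type
    table = SynapseTable(
        pre=cat["pre"],
        post=cat["post"],
        weight=cat["weight"],
        delay=cat["delay"],
        receptor=cat["receptor"],
        plastic=_plastic_flags(ct[cat["pre"]], ct[cat["post"]]),
        g0=cat["g0"],
        cell_type_pre=ct[cat["pre"]],
        cell_type_post=ct[cat["post"]],
        receptor_params=(AMPA, GABA_A),
        conductance_mode=True,
    )
    return NetworkSpec(
        neurons=neurons,
        synapses=table,
        metadata={
            "kind": "multilayer",
            "layer_labels": labels,
            "layer_size": layer_size,
            "p_inter": adjacency.p,
            "seed": seed,
        },
    )
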