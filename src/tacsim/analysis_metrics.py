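"""Summary statistics of simulation runs.

Firing rates, stimulation-phase histograms with vector strength, phase
response maps, spike-timing-difference distributions f(dT), membrane-
timescale group assignment, grouped weight-distribution trajectories and net
weight-change matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_dynamics import NeuronParams, NoiseSpec, SpikeRecord, StimulusSpec
from .plasticity import DeltaTHistogram

__all__ = [
    "MTCGroups",
    "PhaseHistogram",
    "firing_rates",
    "phase_histogram",
    "phase_response_map",
    "delta_t_histogram",
    "weight_trajectory",
    "net_weight_change",
    "bootstrap_ci",
]


def bootstrap_ci(
    values: np.ndarray,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean of ``values``.

    Used to decide whether a trial-averaged weight change is resolved above
    trial noise before comparing its sign with the timing-distribution
    predictor.
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need at least two values")
    rng = np.random.default_rng(seed)
    means = rng.choice(values, size=(n_boot, values.size), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(means, alpha)), float(np.quantile(means, 1.0 - alpha))

#: group labels used throughout: fast, mid (near-mean) and slow timescales
GROUP_FAST, GROUP_MID, GROUP_SLOW, GROUP_NONE = "fast", "mid", "slow", "unassigned"


@dataclass
class MTCGroups:
    """Timescale classification of neurons.

    Default thresholds follow the study: fast tau <= 8 ms, mid (near the
    10 ms mean) tau in [9.5, 10.5] ms, slow tau >= 12 ms.  Neurons between
    the bands simulate but are excluded from group summaries.
    """

    labels: np.ndarray
    fast_max: float = 8.0
    mid_range: tuple[float, float] = (9.5, 10.5)
    slow_min: float = 12.0

    @classmethod
    def from_tau(
        cls,
        tau_m: np.ndarray,
        fast_max: float = 8.0,
        mid_range: tuple[float, float] = (9.5, 10.5),
        slow_min: float = 12.0,
    ) -> "MTCGroups":
        tau = np.asarray(tau_m, float)
        labels = np.full(tau.shape, GROUP_NONE, dtype=object)
        labels[tau <= fast_max] = GROUP_FAST
        labels[(tau >= mid_range[0]) & (tau <= mid_range[1])] = GROUP_MID
        labels[tau >= slow_min] = GROUP_SLOW
        return cls(labels=labels, fast_max=fast_max, mid_range=mid_range, slow_min=slow_min)

    def members(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.labels == group)


@dataclass
class PhaseHistogram:
    """Histogram of spike phases relative to the stimulation cycle.

    ``vector_strength`` is the resultant length of the spike phases on the
    unit circle (0 = uniform firing, 1 = perfect locking);
    ``mean_phase`` is the circular mean (NaN when no spikes contribute).
    """

    edges: np.ndarray
    counts: np.ndarray
    vector_strength: float
    mean_phase: float

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.vector_strength <= 1.0 + 1e-12:
            raise ValueError("vector strength must lie in [0, 1]")


def firing_rates(spikes: SpikeRecord, window: tuple[float, float]) -> np.ndarray:
    """Per-neuron firing rate (Hz) over the window (t0, t1) in ms."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    m = (spikes.times >= t0) & (spikes.times < t1)
    counts = np.bincount(spikes.ids[m], minlength=spikes.n_neurons)
    return counts / ((t1 - t0) / 1000.0)


def spike_phases(times_ms: np.ndarray, stim: StimulusSpec) -> np.ndarray:
    """Stimulation phase (2 pi omega_s t + theta) mod 2 pi of each spike time."""
    if stim.frequency <= 0:
        raise ValueError("stimulation frequency must be positive")
    return np.mod(2.0 * np.pi * stim.frequency * (np.asarray(times_ms, float) / 1000.0)
                  + stim.phase, 2.0 * np.pi)


def phase_histogram(spikes: SpikeRecord, stim: StimulusSpec, bins: int = 36) -> PhaseHistogram:
    """Distribution of spike times over the stimulation phase.

    The vector strength is computed from the exact spike phases (not the
    binned counts) and is invariant to the global phase offset theta.
    """
    ph = spike_phases(spikes.times, stim)
    counts, edges = np.histogram(ph, bins=bins, range=(0.0, 2.0 * np.pi))
    if ph.size:
        z = np.exp(1j * ph).mean()
        vs, mean_phase = float(abs(z)), float(np.angle(z) % (2 * np.pi))
    else:
        vs, mean_phase = 0.0, float("nan")
    return PhaseHistogram(edges=edges, counts=counts, vector_strength=vs, mean_phase=mean_phase)


def phase_response_map(
    tau_grid: Sequence[float],
    omega_grid: Sequence[float],
    amplitude: float = 1.0,
    noise: NoiseSpec | None = None,
    duration_s: float = 10.0,
    n_trials: int = 10,
    seed: int = 0,
    dt: float = 0.1,
) -> dict[str, np.ndarray]:
    """Circular-mean firing phase and mean rate per (tau_m, omega_s) cell.

    Each cell simulates ``n_trials`` independent stimulated neurons for
    ``duration_s`` seconds.  Cells whose firing shows no phase preference
    (sham, or no spikes) report NaN mean phase.  Returns arrays of shape
    (len(tau_grid), len(omega_grid)): ``mean_phase``, ``rate``,
    ``vector_strength``.
    """
    from ._engine import simulate_unconnected

    noise = noise or NoiseSpec()
    taus = np.asarray(tau_grid, float)
    omegas = np.asarray(omega_grid, float)
    shape = (taus.size, omegas.size)
    mean_phase = np.full(shape, np.nan)
    rate = np.zeros(shape)
    vstr = np.zeros(shape)
    for j, om in enumerate(omegas):
        stim = StimulusSpec(amplitude=amplitude, frequency=om, t_on=0.0, t_off=duration_s)
        res = simulate_unconnected(
            tau_m=np.repeat(taus, n_trials),
            rheo=np.zeros(taus.size * n_trials),
            v_rest=np.full(taus.size * n_trials, -60.0),
            v_thr=-54.0,
            tau_ref=2.0,
            mu=noise.mu,
            sigma=noise.sigma,
            stim=stim,
            duration_s=duration_s,
            dt=dt,
            seed=seed + j,
            record_spikes=True,
        )
        rate[:, j] = res.counts.reshape(taus.size, n_trials).mean(axis=1) / duration_s
        cell = res.spike_ids // n_trials
        for i in range(taus.size):
            tms = res.spike_times[cell == i]
            if tms.size == 0:
                continue
            z = np.exp(1j * spike_phases(tms, stim)).mean()
            vstr[i, j] = abs(z)
            mean_phase[i, j] = float(np.angle(z) % (2 * np.pi))
    return {"mean_phase": mean_phase, "rate": rate, "vector_strength": vstr,
            "tau_grid": taus, "omega_grid": omegas}


def delta_t_histogram(
    pre_times: np.ndarray,
    post_times: np.ndarray,
    window: float = 100.0,
    bin_width: float = 1.0,
) -> DeltaTHistogram:
    """Normalised distribution of dT = t_post - t_pre over all cross pairs.

    Every (pre, post) spike pair with |dT| <= window (ms) contributes once.
    The window default of 100 ms exceeds ten STDP decay constants, so the
    truncation error on the predicted mean weight change is negligible.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    pre = np.sort(np.asarray(pre_times, float))
    post = np.asarray(post_times, float)
    n_bins = int(round(2 * window / bin_width))
    edges = np.linspace(-window, window, n_bins + 1)
    counts = np.zeros(n_bins)
    # windowed pairing via binary search keeps this O(n log n + pairs)
    lo = np.searchsorted(pre, post - window, side="left")
    hi = np.searchsorted(pre, post + window, side="right")
    for t_post, a, b in zip(post, lo, hi):
        if b > a:
            d = t_post - pre[a:b]
            c, _ = np.histogram(d, bins=edges)
            counts += c
    total = counts.sum()
    if total > 0:
        density = counts / (total * bin_width)
    else:
        density = np.full(n_bins, 1.0 / (2 * window))  # no pairs: flat reference
    return DeltaTHistogram(edges=edges, density=density, window=window)


def weight_trajectory(
    snapshot_times: np.ndarray,
    weight_snaps: np.ndarray,
    table,
    groups: MTCGroups,
) -> dict[tuple, dict[str, np.ndarray]]:
    """Per-(pre-group, post-group, pre-type, post-type) weight statistics.

    ``weight_snaps`` has shape (n_snapshots, n_synapses).  For every
    combination with at least one synapse the result maps
    (pre_group, post_group, pre_type, post_type) -> dict with ``times``,
    ``mean``, ``sd`` arrays over snapshots.  Cell types are "E"/"I".
    """
    snapshot_times = np.asarray(snapshot_times, float)
    weight_snaps = np.asarray(weight_snaps, float)
    if weight_snaps.ndim != 2 or weight_snaps.shape[0] != snapshot_times.size:
        raise ValueError("weight_snaps must be (n_snapshots, n_synapses)")
    pre_g = groups.labels[table.pre]
    post_g = groups.labels[table.post]
    type_name = np.array(["E", "I"])
    pre_t = type_name[table.cell_type_pre]
    post_t = type_name[table.cell_type_post]
    out: dict[tuple, dict[str, np.ndarray]] = {}
    for pg in (GROUP_FAST, GROUP_MID, GROUP_SLOW):
        for qg in (GROUP_FAST, GROUP_MID, GROUP_SLOW):
            for pt in ("E", "I"):
                for qt in ("E", "I"):
                    sel = (pre_g == pg) & (post_g == qg) & (pre_t == pt) & (post_t == qt)
                    if not sel.any():
                        continue
                    w = weight_snaps[:, sel]
                    out[(pg, qg, pt, qt)] = {
                        "times": snapshot_times,
                        "mean": w.mean(axis=1),
                        "sd": w.std(axis=1),
                        "n_synapses": int(sel.sum()),
                    }
    return out


def net_weight_change(
    initial: np.ndarray,
    final: np.ndarray,
    table,
    tau_m: np.ndarray | None = None,
    min_mtc_gap: float | None = None,
    layers: np.ndarray | None = None,
    layer_pair: tuple[int, int] | None = None,
    excitatory_only: bool = False,
) -> float:
    """Sum of final minus initial weights over the selected synapses.

    Selectors compose: ``min_mtc_gap`` keeps synapses whose pre/post membrane
    time constants differ by at least that many ms; ``layer_pair`` (with the
    per-neuron ``layers`` index array) keeps synapses from one layer to
    another; ``excitatory_only`` keeps synapses with excitatory pre and post
    cells.
    """
    initial = np.asarray(initial, float)
    final = np.asarray(final, float)
    if initial.shape != final.shape or initial.size != len(table):
        raise ValueError("initial/final weight vectors must match the synapse table")
    sel = np.ones(len(table), bool)
    if min_mtc_gap is not None:
        if tau_m is None:
            raise ValueError("tau_m required for an MTC-gap selector")
        tau = np.asarray(tau_m, float)
        sel &= np.abs(tau[table.post] - tau[table.pre]) >= min_mtc_gap
    if layer_pair is not None:
        if layers is None:
            raise ValueError("layers required for a layer-pair selector")
        lay = np.asarray(layers)
        sel &= (lay[table.pre] == layer_pair[0]) & (lay[table.post] == layer_pair[1])
    if excitatory_only:
        sel &= (table.cell_type_pre == 0) & (table.cell_type_post == 0)
    return float(np.sum(final[sel]) - np.sum(initial[sel]))
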