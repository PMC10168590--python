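"""Experiment orchestration: epoched runs, pair-motif sweeps, laminar sweeps.

The canonical protocol simulates a network for ``t_total`` seconds with the
stimulation switched on between ``t_pre_end`` and ``t_stim_end`` (the study's
full-length schedule is 4 s / 40 s / 60 s), with spike-timing-dependent
plasticity active throughout and weight snapshots taken at a configurable
cadence.  Sweeps repeat the protocol over stimulation-frequency grids and
either postsynaptic-timescale grids (two-neuron motif) or ordered layer pairs
(laminar network), averaging over independent trials whose child seeds derive
deterministically from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import analysis_metrics as am
from ._engine import run_network
from .core_dynamics import NoiseSpec, SpikeRecord, StimulusSpec
from .network_builders import (
    LaminarAdjacency,
    LayerConfig,
    NetworkSpec,
    build_multilayer,
    build_pair_motif,
)
from .plasticity import STDPParams
from .synthetic_inputs import LayerProfile, layer_profiles

__all__ = [
    "EpochSchedule",
    "SimulationRecord",
    "SweepResult",
    "run_protocol",
    "sweep_pair",
    "sweep_interlaminar",
    "child_seeds",
]


@dataclass(frozen=True)
class EpochSchedule:
    """Pre / stimulation / post epochs in seconds (defaults: 4, 40, 60)."""

    t_pre_end: float = 4.0
    t_stim_end: float = 40.0
    t_total: float = 60.0

    def __post_init__(self) -> None:
        if not (0 < self.t_pre_end <= self.t_stim_end <= self.t_total):
            raise ValueError("require 0 < t_pre_end <= t_stim_end <= t_total")

    def stim_window_ms(self) -> tuple[float, float]:
        return self.t_pre_end * 1000.0, self.t_stim_end * 1000.0


@dataclass
class SimulationRecord:
    """Everything recorded in one protocol run."""

    spikes: SpikeRecord
    snapshot_times: np.ndarray  # seconds
    weight_snaps: np.ndarray  # (n_snapshots, n_synapses)
    initial_weights: np.ndarray
    drive_traces: np.ndarray | None
    drive_group_names: tuple[str, ...]
    network: NetworkSpec
    schedule: EpochSchedule
    stim: StimulusSpec
    seed: int
    dt: float

    def snaps_between(self, t0_s: float, t1_s: float) -> np.ndarray:
        """Weight snapshots with t0 <= t <= t1 (seconds)."""
        m = (self.snapshot_times >= t0_s - 1e-9) & (self.snapshot_times <= t1_s + 1e-9)
        return self.weight_snaps[m]


@dataclass
class SweepResult:
    """Trial-averaged weight changes on a (frequency x condition) grid."""

    omega_grid: np.ndarray
    cell_axis: np.ndarray | list
    mean_change: np.ndarray  # (len(cell_axis), len(omega_grid))
    trial_sd: np.ndarray
    trial_values: np.ndarray  # (len(cell_axis), len(omega_grid), n_trials)
    n_trials: int
    seeds: np.ndarray

    def __post_init__(self) -> None:
        if self.mean_change.shape != self.trial_sd.shape:
            raise ValueError("grid shapes inconsistent")
        if np.any(self.trial_sd < 0):
            raise ValueError("trial sd must be non-negative")


def child_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-trial seeds derived from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n) % (2**31 - 1)


def run_protocol(
    network: NetworkSpec,
    schedule: EpochSchedule,
    stim: StimulusSpec,
    seed: int,
    noise: NoiseSpec | None = None,
    stdp: STDPParams | None = None,
    snapshot_every_s: float = 0.5,
    record_groups: bool = False,
    dt: float = 0.1,
    spike_rate_cap_hz: float = 200.0,
) -> SimulationRecord:
    """Simulate one epoched run with plasticity active throughout.

    The stimulation window is taken from the schedule (overriding any window
    on ``stim``); amplitude 0 is the sham condition and produces a run that
    is bit-identical to a zero-length stimulation window with the same seed.
    ``record_groups`` additionally records mean synaptic-drive traces per
    (cell type x timescale group).
    """
    noise = noise or NoiseSpec()
    stdp = stdp if stdp is not None else STDPParams()
    stim = replace(stim, t_on=schedule.t_pre_end, t_off=schedule.t_stim_end)

    group_id = None
    n_groups = 0
    group_names: tuple[str, ...] = ()
    if record_groups:
        groups = am.MTCGroups.from_tau(network.neurons.tau_m)
        names = []
        gid = np.full(network.neurons.n, -1, np.int64)
        for ct, ct_name in ((0, "E"), (1, "I")):
            for g in (am.GROUP_FAST, am.GROUP_MID, am.GROUP_SLOW):
                sel = (network.neurons.cell_type == ct) & (groups.labels == g)
                if sel.any():
                    gid[sel] = len(names)
                    names.append(f"{ct_name}_{g}")
        group_id, n_groups, group_names = gid, len(names), tuple(names)

    initial = network.synapses.weight.copy()
    snap_times = np.arange(snapshot_every_s, schedule.t_total + 1e-9, snapshot_every_s)
    res = run_network(
        network,
        stim,
        noise,
        schedule.t_total,
        seed,
        dt=dt,
        stdp=stdp,
        snapshot_times_s=snap_times,
        group_id=group_id,
        n_groups=n_groups,
        spike_rate_cap_hz=spike_rate_cap_hz,
    )
    drive = None
    if record_groups and n_groups:
        sizes = np.bincount(group_id[group_id >= 0], minlength=n_groups)
        drive = res.drive_traces / np.maximum(sizes, 1)
    spikes = SpikeRecord(
        ids=res.spike_ids,
        times=res.spike_times,
        duration=schedule.t_total * 1000.0,
        n_neurons=network.neurons.n,
    )
    return SimulationRecord(
        spikes=spikes,
        snapshot_times=snap_times,
        weight_snaps=res.weight_snaps,
        initial_weights=initial,
        drive_traces=drive,
        drive_group_names=group_names,
        network=network,
        schedule=schedule,
        stim=stim,
        seed=seed,
        dt=dt,
    )


def _stim_end_weight(record: SimulationRecord, readout_window_s: float = 5.0) -> np.ndarray:
    """Per-synapse weight averaged over snapshots in the last part of stimulation.

    Follows the study's readout: weights averaged at the snapshot cadence over
    the final ``readout_window_s`` seconds of the stimulation epoch.
    """
    t1 = record.schedule.t_stim_end
    t0 = max(record.schedule.t_pre_end, t1 - readout_window_s)
    snaps = record.snaps_between(t0, t1)
    if snaps.shape[0] == 0:
        raise ValueError("no snapshots inside the readout window")
    return snaps.mean(axis=0)


def sweep_pair(
    tau_pre: float,
    tau_post_grid: Sequence[float],
    omega_grid: Sequence[float],
    amplitude: float = 1.0,
    noise: NoiseSpec | None = None,
    schedule: EpochSchedule | None = None,
    n_trials: int = 10,
    master_seed: int = 0,
    readout_window_s: float = 5.0,
    snapshot_every_s: float = 0.5,
    stdp: STDPParams | None = None,
    dt: float = 0.1,
) -> SweepResult:
    """Weight change of the 1->2 synapse across (tau_post, omega_s) cells.

    Each cell runs ``n_trials`` independent trials of the epoched protocol on
    a freshly built two-neuron motif; the readout is the stimulation-end
    average of the forward weight minus its initial value.
    """
    taus = np.asarray(tau_post_grid, float)
    omegas = np.asarray(omega_grid, float)
    if taus.size == 0 or omegas.size == 0:
        raise ValueError("grids must be non-empty")
    noise = noise or NoiseSpec()
    schedule = schedule or EpochSchedule()
    stdp = stdp if stdp is not None else STDPParams(g_0=0.1)
    seeds = child_seeds(master_seed, n_trials)
    vals = np.zeros((taus.size, omegas.size, n_trials))
    for i, tp in enumerate(taus):
        for j, om in enumerate(omegas):
            for k, s in enumerate(seeds):
                net = build_pair_motif(tau_pre, tp)
                stim = StimulusSpec(amplitude=amplitude, frequency=om)
                rec = run_protocol(
                    net,
                    schedule,
                    stim,
                    int(s),
                    noise=noise,
                    stdp=stdp,
                    snapshot_every_s=snapshot_every_s,
                    dt=dt,
                )
                wf = _stim_end_weight(rec, readout_window_s)
                fwd = 0  # synapse 0 is 1->2 by construction
                vals[i, j, k] = wf[fwd] - rec.initial_weights[fwd]
    return SweepResult(
        omega_grid=omegas,
        cell_axis=taus,
        mean_change=vals.mean(axis=2),
        trial_sd=vals.std(axis=2, ddof=1) if n_trials > 1 else np.zeros(vals.shape[:2]),
        trial_values=vals,
        n_trials=n_trials,
        seeds=seeds,
    )


def sweep_interlaminar(
    omega_grid: Sequence[float],
    layer_size: int = 600,
    profiles: Sequence[LayerProfile] | None = None,
    adjacency: LaminarAdjacency | None = None,
    layer_config: LayerConfig | None = None,
    amplitude: float = 1.0,
    noise: NoiseSpec | None = None,
    schedule: EpochSchedule | None = None,
    n_trials: int = 5,
    master_seed: int = 0,
    min_mtc_gap: float = 5.0,
    readout_window_s: float = 5.0,
    snapshot_every_s: float = 0.5,
    stdp: STDPParams | None = None,
    dt: float = 0.1,
) -> SweepResult:
    """Net weight change per (omega_s, ordered layer pair) on the laminar net.

    For each frequency and trial a fresh four-layer network runs the epoched
    protocol; per ordered layer pair (including intra-laminar diagonal cells)
    the readout sums stimulation-end minus initial weights over excitatory
    synapses whose pre/post membrane time constants differ by at least
    ``min_mtc_gap`` ms.  ``cell_axis`` lists the (src, dst) label pairs.
    """
    omegas = np.asarray(omega_grid, float)
    if omegas.size == 0:
        raise ValueError("omega grid must be non-empty")
    noise = noise or NoiseSpec()
    schedule = schedule or EpochSchedule()
    stdp = stdp if stdp is not None else STDPParams()
    profiles = list(profiles) if profiles is not None else layer_profiles()
    labels = [p.label for p in profiles]
    pairs = [(a, b) for a in range(4) for b in range(4)]
    seeds = child_seeds(master_seed, n_trials)
    vals = np.zeros((len(pairs), omegas.size, n_trials))
    for j, om in enumerate(omegas):
        for k, s in enumerate(seeds):
            net = build_multilayer(
                layer_size=layer_size,
                profiles=profiles,
                adjacency=adjacency,
                layer_config=layer_config,
                seed=int(s),
            )
            stim = StimulusSpec(amplitude=amplitude, frequency=om)
            rec = run_protocol(
                net,
                schedule,
                stim,
                int(s) + j,
                noise=noise,
                stdp=stdp,
                snapshot_every_s=snapshot_every_s,
                dt=dt,
            )
            wf = _stim_end_weight(rec, readout_window_s)
            for pi, (a, b) in enumerate(pairs):
                vals[pi, j, k] = am.net_weight_change(
                    rec.initial_weights,
                    wf,
                    net.synapses,
                    tau_m=net.neurons.tau_m,
                    min_mtc_gap=min_mtc_gap,
                    layers=net.neurons.layer,
                    layer_pair=(a, b),
                    excitatory_only=True,
                )
    return SweepResult(
        omega_grid=omegas,
        cell_axis=[(labels[a], labels[b]) for a, b in pairs],
        mean_change=vals.mean(axis=2),
        trial_sd=vals.std(axis=2, ddof=1) if n_trials > 1 else np.zeros(vals.shape[:2]),
        trial_values=vals,
        n_trials=n_trials,
        seeds=seeds,
    )
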