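"""Vectorised network integration fast path (numba-jitted).

Implements exactly the update scheme of the scalar reference in
:mod:`tacsim.core_dynamics` / :mod:`tacsim.plasticity`, for whole networks:

per time step ``k`` (t = k dt):

1. deliver delayed spike arrivals from the ring buffer into per-neuron
   double-exponential conductance accumulators (one pair per receptor class);
2. Euler--Maruyama step of every non-refractory membrane, threshold test,
   reset and refractory clamp;
3. decay the STDP eligibility traces, apply potentiation (spikers as
   postsynaptic partners) then depression (spikers as presynaptic partners)
   with per-event clipping, then add the new spikes to the traces -- this is
   the all-to-all pairing rule in O(fan-in + fan-out) per spike, with
   coincident (dT = 0) pairs contributing nothing;
4. enqueue the spikes' synaptic arrivals at their axonal delays.

The double-exponential kernel (exp(-s/tau_d) - exp(-s/tau_r))/K is realised
by two exponential accumulators per neuron and receptor, which equals direct
summation over the spike history up to floating-point round-off.

Everything is deterministic given the seed (single-threaded, legacy numpy
RNG seeded inside the jitted function).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core_dynamics import StimulusSpec

__all__ = ["EngineResult", "run_network", "simulate_unconnected", "simulate_passive_trace"]

#: error codes returned by the core loop
_OK, _ERR_SPIKE_OVERFLOW, _ERR_NONFINITE = 0, 1, 2


@njit(cache=True)
def _run_core(
    tau_m,
    v_rest,
    rheo,
    v_thr,
    ref_steps,
    dt,
    mu,
    sigma,
    syn_pre,
    syn_post,
    syn_w,
    syn_delay_steps,
    syn_rec,
    syn_plastic,
    syn_g0,
    syn_gmin,
    syn_gmax,
    indptr_pre,
    indptr_post,
    syn_by_post,
    tau_r,
    tau_d,
    e_syn,
    norm,
    conductance_mode,
    amp,
    freq_hz,
    theta,
    t_on_ms,
    t_off_ms,
    stdp_on,
    a_plus,
    a_minus,
    gam_p,
    gam_m,
    n_steps,
    seed,
    snap_steps,
    group_id,
    n_groups,
    max_spikes,
    record_spikes,
    record_v,
):
    n = tau_m.size
    m = syn_post.size
    np.random.seed(seed)

    # a spike emitted at step k carries time (k+1) dt; its arrival enters the
    # accumulators at step k+1+delay so the kernel argument equals
    # t - t_spike - t_delay exactly
    max_d = 2
    for s in range(m):
        if syn_delay_steps[s] + 2 > max_d:
            max_d = syn_delay_steps[s] + 2
    ring = np.zeros((max_d, n, 2))
    xd = np.zeros((n, 2))
    xr = np.zeros((n, 2))
    dec_d = np.exp(-dt / tau_d)
    dec_r = np.exp(-dt / tau_r)
    dec_tp = np.exp(-dt / gam_p)
    dec_tm = np.exp(-dt / gam_m)
    trace_pre = np.zeros(n)
    trace_post = np.zeros(n)

    v = v_rest.copy()
    refr = np.zeros(n, np.int64)
    counts = np.zeros(n, np.int64)
    spk_id = np.empty(max_spikes, np.int64)
    spk_t = np.empty(max_spikes, np.float64)
    n_spk = 0
    spikers = np.empty(n, np.int64)
    w_snaps = np.zeros((snap_steps.size, m))
    snap_ptr = 0
    drive_tr = np.zeros((n_steps if n_groups > 0 else 0, n_groups))
    v_tr = np.zeros(n_steps if record_v >= 0 else 0)

    sqdt = np.sqrt(dt)
    two_pi = 2.0 * np.pi
    err = _OK

    for k in range(n_steps):
        slot = k % max_d
        for i in range(n):
            a0 = ring[slot, i, 0]
            a1 = ring[slot, i, 1]
            xd[i, 0] = xd[i, 0] * dec_d[0] + a0
            xr[i, 0] = xr[i, 0] * dec_r[0] + a0
            xd[i, 1] = xd[i, 1] * dec_d[1] + a1
            xr[i, 1] = xr[i, 1] * dec_r[1] + a1
            ring[slot, i, 0] = 0.0
            ring[slot, i, 1] = 0.0

        t = k * dt
        stim_cur = 0.0
        if amp > 0.0 and t_on_ms <= t < t_off_ms:
            stim_cur = amp * np.sin(two_pi * freq_hz * t * 0.001 + theta)

        nsp = 0
        for i in range(n):
            ge = (xd[i, 0] - xr[i, 0]) / norm[0]
            gi = (xd[i, 1] - xr[i, 1]) / norm[1]
            if conductance_mode:
                drive = ge * (e_syn[0] - v[i]) + gi * (e_syn[1] - v[i])
            else:
                drive = ge + gi
            if n_groups > 0 and group_id[i] >= 0:
                drive_tr[k, group_id[i]] += drive
            if refr[i] > 0:
                refr[i] -= 1
                v[i] = v_rest[i]
                continue
            xi = np.random.standard_normal() if sigma > 0.0 else 0.0
            v[i] += (dt / tau_m[i]) * (
                v_rest[i] - v[i] + mu + rheo[i] + drive + stim_cur
            ) + (sigma / tau_m[i]) * sqdt * xi
            if not np.isfinite(v[i]):
                err = _ERR_NONFINITE
                break
            if v[i] >= v_thr:
                v[i] = v_rest[i]
                refr[i] = ref_steps
                counts[i] += 1
                spikers[nsp] = i
                nsp += 1
                if record_spikes:
                    if n_spk >= max_spikes:
                        err = _ERR_SPIKE_OVERFLOW
                        break
                    spk_id[n_spk] = i
                    spk_t[n_spk] = (k + 1) * dt
                    n_spk += 1
        if err != _OK:
            break
        if record_v >= 0:
            v_tr[k] = v[record_v]

        if stdp_on:
            for i in range(n):
                trace_pre[i] *= dec_tp
                trace_post[i] *= dec_tm
            if nsp > 0:
                # potentiation: spiker is the postsynaptic partner
                for s in range(nsp):
                    i = spikers[s]
                    for kk in range(indptr_post[i], indptr_post[i + 1]):
                        sy = syn_by_post[kk]
                        if syn_plastic[sy]:
                            w = syn_w[sy] + a_plus * syn_g0[sy] * (
                                1.0 - syn_w[sy] / syn_gmax[sy]
                            ) * trace_pre[syn_pre[sy]]
                            if w > syn_gmax[sy]:
                                w = syn_gmax[sy]
                            elif w < syn_gmin[sy]:
                                w = syn_gmin[sy]
                            syn_w[sy] = w
                # depression: spiker is the presynaptic partner
                for s in range(nsp):
                    j = spikers[s]
                    for sy in range(indptr_pre[j], indptr_pre[j + 1]):
                        if syn_plastic[sy]:
                            w = syn_w[sy] - a_minus * syn_w[sy] * trace_post[syn_post[sy]]
                            if w > syn_gmax[sy]:
                                w = syn_gmax[sy]
                            elif w < syn_gmin[sy]:
                                w = syn_gmin[sy]
                            syn_w[sy] = w
                for s in range(nsp):
                    trace_pre[spikers[s]] += 1.0
                    trace_post[spikers[s]] += 1.0

        # transmission at the weight in effect when the spike leaves the soma
        for s in range(nsp):
            j = spikers[s]
            for sy in range(indptr_pre[j], indptr_pre[j + 1]):
                ring[
                    (k + 1 + syn_delay_steps[sy]) % max_d, syn_post[sy], syn_rec[sy]
                ] += syn_w[sy]

        if snap_ptr < snap_steps.size and k == snap_steps[snap_ptr]:
            for sy in range(m):
                w_snaps[snap_ptr, sy] = syn_w[sy]
            snap_ptr += 1

    return spk_id[:n_spk], spk_t[:n_spk], counts, w_snaps, drive_tr, v_tr, err


class EngineResult:
    """Raw arrays returned by one engine run."""

    def __init__(self, spike_ids, spike_times, counts, weight_snaps, drive_traces, v_trace, n_steps, dt):
        self.spike_ids = spike_ids
        self.spike_times = spike_times
        self.counts = counts
        self.weight_snaps = weight_snaps
        self.drive_traces = drive_traces
        self.v_trace = v_trace
        self.n_steps = n_steps
        self.dt = dt


def run_network(
    network,
    stim: StimulusSpec,
    noise,
    duration_s: float,
    seed: int,
    dt: float = 0.1,
    stdp=None,
    snapshot_times_s=(),
    group_id=None,
    n_groups: int = 0,
    record_spikes: bool = True,
    record_v: int = -1,
    spike_rate_cap_hz: float = 200.0,
    v_thr_override: float | None = None,
) -> EngineResult:
    """Run a compiled network; mutates ``network.synapses.weight`` in place.

    ``stdp`` is an :class:`tacsim.plasticity.STDPParams` (rates and trace
    constants; per-synapse bounds come from the synapse table) or ``None`` to
    freeze all weights.  ``snapshot_times_s`` requests full weight-vector
    snapshots at those times.  ``group_id``/``n_groups`` enable per-group
    mean synaptic-drive traces.  Raises on numerical blow-up or spike-buffer
    overflow.
    """
    neurons = network.neurons
    tab = network.synapses
    n = neurons.n
    m = len(tab)
    n_steps = int(round(duration_s * 1000.0 / dt))

    order = np.argsort(tab.pre, kind="stable")
    syn_pre = tab.pre[order]
    syn_post = tab.post[order]
    syn_w = tab.weight[order].astype(np.float64)
    syn_delay_steps = np.maximum(0, np.round(tab.delay[order] / dt).astype(np.int64))
    syn_rec = tab.receptor[order].astype(np.int64)
    syn_plastic = tab.plastic[order]
    syn_g0 = tab.g0[order]
    syn_gmin = tab.g_min[order]
    syn_gmax = tab.g_max[order]
    indptr_pre = np.zeros(n + 1, np.int64)
    np.add.at(indptr_pre[1:], syn_pre, 1)
    indptr_pre = np.cumsum(indptr_pre)
    post_order = np.argsort(syn_post, kind="stable")
    syn_by_post = post_order.astype(np.int64)
    indptr_post = np.zeros(n + 1, np.int64)
    np.add.at(indptr_post[1:], syn_post, 1)
    indptr_post = np.cumsum(indptr_post)

    pr = tab.receptor_params
    tau_r = np.array([p.tau_r for p in pr], float)
    tau_d = np.array([p.tau_d for p in pr], float)
    e_syn = np.array([p.e_syn for p in pr], float)
    from .synapses import kernel_norm

    norm = np.array([kernel_norm(p) for p in pr], float)

    if group_id is None:
        group_id = np.full(n, -1, np.int64)
        n_groups = 0

    snap_steps = np.array(
        sorted(int(round(ts * 1000.0 / dt)) - 1 for ts in snapshot_times_s), np.int64
    )
    if np.any(snap_steps < 0) or np.any(snap_steps >= n_steps):
        raise ValueError("snapshot times must lie inside the run")

    max_spikes = int(max(100_000, n * duration_s * spike_rate_cap_hz)) if record_spikes else 1

    spk_id, spk_t, counts, w_snaps, drive_tr, v_tr, err = _run_core(
        neurons.tau_m.astype(np.float64),
        neurons.v_rest.astype(np.float64),
        neurons.rheobase_offset.astype(np.float64),
        float(neurons.v_thr) if v_thr_override is None else float(v_thr_override),
        int(round(neurons.tau_ref / dt)),
        float(dt),
        float(noise.mu),
        float(noise.sigma),
        syn_pre.astype(np.int64),
        syn_post.astype(np.int64),
        syn_w,
        syn_delay_steps,
        syn_rec,
        syn_plastic,
        syn_g0.astype(np.float64),
        syn_gmin.astype(np.float64),
        syn_gmax.astype(np.float64),
        indptr_pre,
        indptr_post,
        syn_by_post,
        tau_r,
        tau_d,
        e_syn,
        norm,
        bool(tab.conductance_mode),
        float(stim.amplitude),
        float(stim.frequency),
        float(stim.phase),
        float(stim.t_on * 1000.0),
        float(stim.t_off * 1000.0),
        stdp is not None,
        float(stdp.a_plus) if stdp is not None else 0.0,
        float(stdp.a_minus) if stdp is not None else 0.0,
        float(stdp.gamma_plus) if stdp is not None else 10.0,
        float(stdp.gamma_minus) if stdp is not None else 10.0,
        n_steps,
        int(seed) % (2**31 - 1),
        snap_steps,
        np.asarray(group_id, np.int64),
        int(n_groups),
        max_spikes,
        bool(record_spikes),
        int(record_v),
    )
    if err == _ERR_NONFINITE:
        raise FloatingPointError("membrane potential diverged (non-finite state)")
    if err == _ERR_SPIKE_OVERFLOW:
        raise RuntimeError(
            "spike buffer overflow; raise spike_rate_cap_hz if rates above "
            f"{spike_rate_cap_hz} Hz are expected"
        )
    # write evolved weights back in original synapse order
    tab.weight[order] = syn_w
    w_back = np.empty_like(w_snaps)
    if w_snaps.size:
        w_back[:, order] = w_snaps
    return EngineResult(spk_id, spk_t, counts, w_back, drive_tr, v_tr, n_steps, dt)


def simulate_unconnected(
    tau_m,
    rheo,
    v_rest,
    v_thr,
    tau_ref,
    mu,
    sigma,
    stim: StimulusSpec,
    duration_s: float,
    dt: float,
    seed: int,
    record_spikes: bool = False,
):
    """Simulate independent LIF neurons; returns counts (or a full result).

    Used for F--I curves, phase-response maps and rheobase calibration where
    no synapses are involved.
    """
    from .network_builders import NeuronArray, NetworkSpec, empty_synapse_table

    n = len(tau_m)
    neurons = NeuronArray(
        tau_m=np.asarray(tau_m, float),
        v_rest=np.asarray(v_rest, float),
        cell_type=np.zeros(n, np.int64),
        layer=np.full(n, -1, np.int64),
        rheobase_offset=np.asarray(rheo, float),
        v_thr=float(v_thr),
        tau_ref=float(tau_ref),
    )
    net = NetworkSpec(neurons=neurons, synapses=empty_synapse_table(), metadata={})
    from .core_dynamics import NoiseSpec

    res = run_network(
        net,
        stim,
        NoiseSpec(mu=mu, sigma=sigma),
        duration_s,
        seed,
        dt=dt,
        stdp=None,
        record_spikes=record_spikes,
        spike_rate_cap_hz=400.0,
    )
    return res if record_spikes else res.counts


def simulate_passive_trace(
    tau_m: float,
    noise,
    stim: StimulusSpec,
    duration_s: float,
    dt: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Voltage trace of one passive (non-spiking) membrane.

    The spike threshold is disabled so the membrane acts as a pure low-pass
    filter of the noise and stimulation currents; used to verify the analytic
    spectral density.
    """
    from .network_builders import NeuronArray, NetworkSpec, empty_synapse_table

    neurons = NeuronArray(
        tau_m=np.array([tau_m], float),
        v_rest=np.array([-60.0]),
        cell_type=np.zeros(1, np.int64),
        layer=np.full(1, -1, np.int64),
        rheobase_offset=np.zeros(1),
        v_thr=-54.0,
        tau_ref=0.0,
    )
    net = NetworkSpec(neurons=neurons, synapses=empty_synapse_table(), metadata={})
    res = run_network(
        net,
        stim,
        noise,
        duration_s,
        seed,
        dt=dt,
        stdp=None,
        record_spikes=False,
        record_v=0,
        v_thr_override=np.inf,
    )
    return res.v_trace
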