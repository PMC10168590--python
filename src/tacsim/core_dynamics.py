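"""Leaky integrate-and-fire membrane dynamics under noise and periodic drive.

The membrane potential of each neuron follows the stochastic equation

    tau_m dv/dt = (V_rest - v) + I_zeta + I_syn + I_s,

where ``I_zeta`` is a Gaussian white-noise input current with mean ``mu`` and
intensity ``sigma``, ``I_syn`` the synaptic drive and ``I_s`` a sinusoidal
stimulation current emulating transcranial alternating current stimulation
(tACS).  Integration uses the Euler--Maruyama scheme with the increment

    dv = (dt/tau_m) (V_rest - v + mu + I_syn + I_s) + (sigma/tau_m) sqrt(dt) N(0,1).

A spike is emitted when ``v`` crosses ``v_thr``; the potential is then clamped
at the resting (reset) value for a refractory period ``tau_ref`` during which
all inputs are ignored.

This module holds the scalar reference integrator together with its analytic
oracles (exponential relaxation, the constant-input inter-spike-interval
formula, and the passive-membrane power spectral density).  The vectorised
network fast path lives in :mod:`tacsim._engine` and is cross-checked against
the functions here by the test suite.

All times are in milliseconds, potentials in millivolts and frequencies in
hertz unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NeuronParams",
    "NoiseSpec",
    "StimulusSpec",
    "NeuronState",
    "SpikeRecord",
    "tacs_current",
    "membrane_step",
    "analytic_decay",
    "analytic_isi",
    "passive_psd",
    "fi_curve",
]

DT_DEFAULT_MS = 0.1


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical parameters of one LIF neuron.

    ``rheobase_offset`` is an additive input-current term (mV) used for
    per-layer excitability calibration; it defaults to zero.
    """

    tau_m: float = 10.0
    v_rest: float = -60.0
    v_thr: float = -54.0
    tau_ref: float = 2.0
    rheobase_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau_m > 0:
            raise ValueError(f"tau_m must be positive, got {self.tau_m}")
        if not self.v_thr > self.v_rest:
            raise ValueError("v_thr must exceed v_rest")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    """White-noise input current: mean ``mu`` (mV) and intensity ``sigma``."""

    mu: float = 5.5
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class StimulusSpec:
    """Sinusoidal stimulation current A_s sin(2 pi omega_s t + theta).

    ``t_on``/``t_off`` delimit the stimulation epoch in seconds; outside the
    half-open window [t_on, t_off) the current is zero.  ``amplitude == 0``
    denotes the sham condition.
    """

    amplitude: float = 0.0
    frequency: float = 0.0
    phase: float = 0.0
    t_on: float = 0.0
    t_off: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.frequency < 0:
            raise ValueError("frequency must be non-negative")
        if self.t_on > self.t_off:
            raise ValueError("t_on must not exceed t_off")

    @staticmethod
    def sham() -> "StimulusSpec":
        return StimulusSpec()


@dataclass
class NeuronState:
    v: float = -60.0
    refractory_remaining: float = 0.0
    last_spike_time: float | None = None


@dataclass
class SpikeRecord:
    """Spike events of one simulation run.

    ``ids`` and ``times`` (ms) are parallel arrays sorted by time then id.
    """

    ids: np.ndarray
    times: np.ndarray
    duration: float
    n_neurons: int

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.ids.shape != self.times.shape:
            raise ValueError("ids and times must have equal length")
        order = np.lexsort((self.ids, self.times))
        self.ids = self.ids[order]
        self.times = self.times[order]

    def __len__(self) -> int:
        return len(self.times)

    def train(self, neuron: int) -> np.ndarray:
        """Spike times (ms) of one neuron."""
        return self.times[self.ids == neuron]

    def window(self, t0: float, t1: float) -> "SpikeRecord":
        """Events with t0 <= t < t1 (ms), re-referenced duration kept absolute."""
        m = (self.times >= t0) & (self.times < t1)
        return SpikeRecord(self.ids[m], self.times[m], self.duration, self.n_neurons)


def tacs_current(t: float | np.ndarray, stim: StimulusSpec) -> float | np.ndarray:
    """Stimulation current (mV) at time ``t`` (ms).

    Returns ``A_s sin(2 pi omega_s t + theta)`` inside [t_on, t_off) and zero
    outside.  ``omega_s`` is in Hz, so ``t`` is converted to seconds.
    """
    t_s = np.asarray(t, dtype=float) / 1000.0
    on = (t_s >= stim.t_on) & (t_s < stim.t_off)
    cur = stim.amplitude * np.sin(2.0 * np.pi * stim.frequency * t_s + stim.phase)
    out = np.where(on, cur, 0.0)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def membrane_step(
    state: NeuronState,
    synaptic_drive: float,
    params: NeuronParams,
    noise: NoiseSpec,
    stim: StimulusSpec,
    t: float,
    dt: float = DT_DEFAULT_MS,
    rng: np.random.Generator | None = None,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by one Euler--Maruyama step; return (state, spiked).

    During the refractory period the potential is clamped at the reset value
    and every input (noise, synaptic, stimulation) is ignored.  Scalar
    reference implementation; the network engine applies the identical scheme.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not math.isfinite(state.v):
        raise FloatingPointError(
            f"non-finite membrane potential v={state.v!r} at t={t} ms"
        )
    if state.refractory_remaining > 0:
        new = NeuronState(
            v=params.v_rest,
            refractory_remaining=max(0.0, state.refractory_remaining - dt),
            last_spike_time=state.last_spike_time,
        )
        return new, False

    xi = 0.0
    if noise.sigma > 0:
        if rng is None:
            raise ValueError("rng required when sigma > 0")
        xi = rng.standard_normal()
    drift = (
        params.v_rest
        - state.v
        + noise.mu
        + params.rheobase_offset
        + synaptic_drive
        + tacs_current(t, stim)
    )
    v = state.v + (dt / params.tau_m) * drift + (noise.sigma / params.tau_m) * math.sqrt(dt) * xi
    if not math.isfinite(v):
        raise FloatingPointError(f"membrane potential diverged at t={t} ms")
    if v >= params.v_thr:
        return (
            NeuronState(
                v=params.v_rest,
                refractory_remaining=params.tau_ref,
                last_spike_time=t + dt,
            ),
            True,
        )
    return NeuronState(v, 0.0, state.last_spike_time), False


def analytic_decay(v0: float, t: float | np.ndarray, params: NeuronParams) -> float | np.ndarray:
    """Closed-form zero-input relaxation: v_rest + (v0 - v_rest) exp(-t/tau_m)."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be non-negative")
    return params.v_rest + (v0 - params.v_rest) * np.exp(-np.asarray(t, float) / params.tau_m)


def analytic_isi(delta_i: float, params: NeuronParams) -> float:
    """Deterministic (sigma = 0) inter-spike interval for constant input.

    For suprathreshold drive ``delta_i > v_thr - v_rest``:

        T = tau_ref + tau_m ln( delta_i / (delta_i - (v_thr - v_rest)) )

    Returns ``inf`` for subthreshold input.
    """
    gap = params.v_thr - params.v_rest
    if delta_i <= gap:
        return math.inf
    return params.tau_ref + params.tau_m * math.log(delta_i / (delta_i - gap))


def passive_psd(
    omega: float | np.ndarray,
    params: NeuronParams,
    noise: NoiseSpec,
    stim: StimulusSpec,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Spectral density of the passive (non-spiking) membrane, mu = 0.

    The membrane acts as a first-order low-pass filter, so the density is
    Lorentzian in shape with half-power frequency 1/(2 pi tau_m):

        S(omega) ~ (1 + 4 pi^2 tau_m^2 omega^2)^-1
                   (2 sigma^2 + (A_s^2/4) [delta(omega - omega_s) + delta(omega + omega_s)])

    Returns ``(continuous, lines)`` where ``continuous`` is the noise-driven
    density evaluated at ``omega`` (Hz, relative units) and ``lines`` lists
    ``(omega_s, line_power)`` discrete spectral lines contributed by the
    sinusoidal drive, kept separate from the continuous part.
    """
    w = np.asarray(omega, dtype=float)
    tau_s = params.tau_m / 1000.0  # omega is in Hz, tau_m in ms
    lorentz = 1.0 / (1.0 + 4.0 * np.pi**2 * tau_s**2 * w**2)
    continuous = lorentz * 2.0 * noise.sigma**2
    lines: list[tuple[float, float]] = []
    if stim.amplitude > 0 and stim.frequency > 0:
        ls = 1.0 / (1.0 + 4.0 * np.pi**2 * tau_s**2 * stim.frequency**2)
        lines.append((stim.frequency, ls * stim.amplitude**2 / 4.0))
    return continuous, lines


def fi_curve(
    delta_i_grid: Sequence[float],
    params: NeuronParams,
    noise: NoiseSpec,
    stim: StimulusSpec,
    duration: float = 10.0,
    n_trials: int = 10,
    rng: np.random.Generator | None = None,
    dt: float = DT_DEFAULT_MS,
) -> np.ndarray:
    """Firing rate (Hz) versus constant input offset ``delta_i`` (mV).

    Each grid point replaces the noise mean by ``delta_i`` and measures
    spike count / duration, averaged over ``n_trials`` independent trials of
    ``duration`` seconds each (the study used 10 s x 10 trials).
    """
    grid = np.asarray(delta_i_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("delta_i_grid must not be empty")
    if duration < 1.0:
        raise ValueError("duration must be at least 1 s")
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    # One unconnected engine neuron per (grid point, trial): the per-neuron
    # rheobase offset carries delta_i - mu so every neuron sees its own drive.
    from ._engine import simulate_unconnected

    taus = np.full(grid.size * n_trials, params.tau_m)
    offsets = np.repeat(grid - noise.mu, n_trials) + params.rheobase_offset
    counts = simulate_unconnected(
        tau_m=taus,
        rheo=offsets,
        v_rest=np.full(taus.size, params.v_rest),
        v_thr=params.v_thr,
        tau_ref=params.tau_ref,
        mu=noise.mu,
        sigma=noise.sigma,
        stim=stim,
        duration_s=duration,
        dt=dt,
        seed=int(rng.integers(2**31 - 1)),
    )
    rates = counts.reshape(grid.size, n_trials) / duration
    return rates.mean(axis=1)
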