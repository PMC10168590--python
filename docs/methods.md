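# Methods

## Membrane model and integration

Neurons are leaky integrate-and-fire units,
`τ_m dv/dt = (V_rest − v) + I_ζ + I_syn + I_s`, integrated with
Euler–Maruyama at dt = 0.1 ms (configurable).  The noise current with mean μ
and intensity σ enters the discrete update as

```
v ← v + (dt/τ_m)(V_rest − v + μ + I_syn + I_s) + (σ/τ_m)·√dt·N(0,1),
```

i.e. σ is the intensity of unit white noise injected as a current.  Under
this convention the stationary voltage fluctuation is σ/√(2 τ_m); at the
reference parameters (τ_m = 10 ms, μ = 5.5 mV, σ = 1 mV, threshold 6 mV
above rest, V_rest reset, τ_ref = 2 ms) a neuron fires at ≈ 5 Hz, which is
the baseline regime of all population experiments.  A spike resets `v` to
the (per-neuron) resting value; during the refractory period the membrane is
clamped there and all inputs, including stimulation, are ignored.  Resting
potentials carry a per-neuron offset drawn uniformly in ±0.2 mV, reused as
the reset value.  A non-finite membrane potential aborts the run with the
last completed snapshot preserved.

Analytic oracles validate the integrator: the zero-input relaxation
`v(t) = V_rest + (v₀ − V_rest)e^(−t/τ_m)` (first-order convergence in dt),
the constant-input inter-spike interval
`T = τ_ref + τ_m ln(ΔI/(ΔI − (v_thr − V_rest)))`, and the passive-membrane
spectral density (below).

## Stimulation

The tACS-like current `I_s = A_s sin(2π ω_s t + θ)` is applied identically
to every neuron inside the half-open window [t_on, t_off); θ defaults to 0.
No electric-field, skull or cell-orientation physics is modelled: A_s is
the *effective* somatic polarization amplitude.  The study regimes are
A_s = 0.5 mV (single-neuron characterisation), 1 mV (population
entrainment) and 0.2 mV (low-amplitude regime).

For a passive (non-spiking) membrane driven by noise plus the sinusoid, the
voltage spectrum is Lorentzian with half-power at 1/(2π τ_m) plus a
discrete line at ω_s:

```
S(ω) ∝ (1 + 4π² τ_m² ω²)^[−1] · (2σ² + (A_s²/4)[δ(ω−ω_s) + δ(ω+ω_s)]).
```

`passive_psd` returns the continuous part and the line entries separately;
the test suite checks a Welch periodogram of a simulated passive trace
against both (fitted corner frequency within 20%, line at ω_s).  Note the
half-power frequency is 1/(2π τ_m), not 1/τ_m; the implementation follows
the formula.

## Synapses

Synaptic activation follows a causal double-exponential kernel
`S(s) ∝ e^(−s/τ_d) − e^(−s/τ_r)`, peak-normalised to 1 so that the weight g
is the peak conductance.  Population networks use the conductance form
`I_syn = Σ g S(·)(E_syn − v)` with AMPA (τ_r = 0.5 ms, τ_d = 3 ms,
E = 0 mV) and GABA_a (τ_r = 0.5 ms, τ_d = 5 ms, E = −85 mV) receptor
classes, so excitation depolarises and inhibition hyperpolarises.  The
two-neuron motif uses a current-based synapse (g in mV multiplies the
kernel directly) with the AMPA kernel shape, baseline g₀ = 0.1 mV and a
fixed 0.5 ms delay; network delays are uniform in [0.5, 1] ms and applied
to every synapse.  Baseline network weights are g₀ = 5·10⁻⁵ (E
presynapse) and 25·10⁻⁵ (I presynapse) with 10% Gaussian jitter.

The engine realises each kernel with two exponential accumulators per
neuron and receptor class plus a ring buffer for delayed arrivals; this is
algebraically identical to direct summation over the spike history and is
verified against it to 1e−9 on a 10-neuron fixture.

## Plasticity

Plastic synapses (E→E, E→I and I→E; I→I is static) follow a soft-bound
symmetric Hebbian STDP rule with all-to-all spike pairing:

```
ΔT > 0:  Δg = +A₊ g₀ (1 − g/g_max) e^(−ΔT/γ₊)
ΔT < 0:  Δg = −A₋ g₀ (g/g₀)       e^(+ΔT/γ₋)
```

A₊ = 2A₋ = 0.02, γ± = 10 ms, g_min = 0.01 g₀, g_max = 2 g₀.  The learning
rates are *fractional* — they scale the class baseline g₀ — so the same
dimensionless parameters produce ~2%-of-baseline steps in both the motif
(g₀ = 0.1 mV) and the population model (g₀ ~ 10⁻⁵ a.u.); treating A₊ as an
absolute weight change would exceed the population weight bounds by two
orders of magnitude in a single pairing.  ΔT = 0 pairs contribute nothing.

Online updates use per-neuron exponential traces (decay γ±): a postsynaptic
spike potentiates each incoming plastic synapse by the presynaptic trace, a
presynaptic spike depresses each outgoing one by the postsynaptic trace.
Within a timestep, potentiation is applied before depression and weights
are clipped into [g_min, g_max] after every event.  The trace formulation
is verified against a brute-force all-pairs summation (clipping disabled)
to 1e−9.

Balancing the two weight-dependent rates under uncorrelated firing gives
the fixed point `A₊(1 − g*/g_max)γ₊ = A₋(g*/g₀)γ₋`; with the defaults
g* = g₀ exactly, which is why sham-condition weight distributions stay
centred on their baseline.

### Predicting the direction of change

Given a measured distribution f(ΔT) of pre/post timing differences, the
expected change per pairing is the rule integrated against f.
`predicted_mean_change` offers two kernels: the bare-amplitude form
(±A± e^(∓ΔT/γ±)), and an operating-point form that evaluates the effective
rates A₊(1 − g/g_max) and A₋(g/g₀) at a chosen weight.  Because A₊ = 2A₋,
the bare form is positively biased even for flat f; the operating-point
form at g = g₀ is balanced and is the predictor whose sign is compared with
simulated weight changes (12/12 sign agreements on the reduced
frequency × timescale grid, with the matched-timescale column statistically
zero).  f(ΔT) uses all cross pairs within a ±100 ms window (> 10 γ±, so
truncation error is negligible) and 1 ms bins.

## Synthetic inputs

All stochastic inputs are pure functions of (spec, seed).

* **Intra-laminar MTCs**: Gaussian, mean 10 ms, sd 3 ms, redrawn (not
  clipped) while at or below the lower bound.  The bound defaults to 1 ms
  purely as a numerical-stability floor (≥ 10 dt); it truncates ~0.13% of
  the mass.  sd = 0 gives the homogeneous control.
* **Layer-specific MTCs**: the empirical layer distributions are available
  only graphically, so the laminar model ships lognormal stand-ins with
  calibration-default (mean ± sd) of III: 8±3, IV: 10±3, V: 15±5,
  VI: 20±6 ms.  These are not measured values; only the superficial-fast /
  deep-slow ordering is treated as a modelling constraint, and every layer
  is configurable.
* **Rheobase calibration**: longer-MTC layers are intrinsically less
  excitable, so each layer's additive input offset is set by bisection until
  a probe population of unconnected neurons with that layer's MTC
  distribution fires at 5 ± 1 Hz under sham input.  This mirrors placing
  all layers in a comparable dynamical regime before stimulation.
* **Initial weights** are Gaussian around g₀ (sd 0.1 g₀) clipped to the
  plasticity bounds; **delays** uniform in the configured range.

### Baseline firing statistics: mean versus mode

The firing rate of an LIF neuron under this noise convention falls steeply
and convexly with τ_m (≈ 16 Hz at 6 ms, 5 Hz at 10 ms, 1.7 Hz at 14 ms;
recurrent input is negligible in the weak-coupling regime).  Consequently
the *population mean* rate of the heterogeneous layer (~7.5 Hz) sits above
its modal and median rate (~5 Hz): the distribution is right-skewed by the
fast-τ tail.  "The network fires around 5 Hz" is accurate for the typical
neuron and for the histogram bulk, but a mean-based summary reads higher;
both numbers are computed and reported by the acceptance machinery.

## Networks and protocols

* **Pair motif**: two excitatory neurons, reciprocal plastic current-based
  synapses.
* **Cortical layer**: N = 2000 at desk scale (the full-scale table value is
  N = 10000, available via configuration), 4:1 E:I split, every ordered
  cell-type pair wired independently at p = 0.1, no self-loops.
* **Laminar network**: four layers (III, IV, V, VI) of 600 neurons each at
  desk scale (full scale 3000), intra-laminar wiring as above,
  inter-laminar E→E connections at p = 0.05 on a configurable adjacency
  that defaults to all ordered layer pairs; inhibitory neurons never
  project across layers.

The canonical protocol runs pre/stim/post epochs (full-length schedule
4 s / 40 s / 60 s) with STDP active throughout and weight snapshots every
500 ms.  The stimulation-end readout averages snapshots over the last 5 s
of the stimulation epoch, and sweeps average 5–10 independent trials whose
child seeds derive deterministically from one master seed.  Weight changes
are summarised per timescale group (fast τ ≤ 8 ms, mid 9.5–10.5 ms, slow
τ ≥ 12 ms; neurons between the bands simulate but are excluded from group
summaries) or, in the laminar analysis, summed over excitatory synapses
whose pre/post MTCs differ by at least 5 ms, per ordered layer pair.

The test suite runs the same protocols at reduced length (typically 2 s
pre, 15 s stimulation, 8 s post for the layer, 12 s total for pair sweeps)
— the entrainment-induced weight shifts saturate within a few seconds, so
these shorter epochs expose the same effects at a fraction of the cost;
the schedule is configurable wherever longer runs are wanted.

## Numerics and determinism

The jitted engine is single-threaded; given identical (config, seed) two
runs produce bit-identical spike records and weights.  Spike times are
quantised to the step grid (a spike detected while integrating step k is
stamped (k+1)·dt, and its synaptic arrivals enter at t_spike + delay).
Trial seeds come from `numpy.random.SeedSequence`.  Spike buffers are
preallocated from a configurable ceiling rate (default 200 Hz per neuron)
and overflow aborts loudly rather than truncating.

## Limitations

* tACS enters as a uniform somatic current: no field geometry, no
  cell-type-specific polarisation, no skull shunting.
* The stimulation amplitudes that produce strong plasticity also raise
  firing rates; the low-amplitude regime preserves the rate distribution
  but yields proportionally small weight shifts.
* Plasticity effects decay after stimulation offset (the rule's fixed point
  pulls weights back to baseline); the model makes no claim about
  persistence beyond that drift.
* Random (Erdős–Rényi-style) wiring, single-compartment neurons, no
  short-term plasticity, triplet STDP or homeostasis; the laminar
  projection pattern is configuration, not anatomy.
* Layer MTC profiles are parametric stand-ins constrained only by ordering.
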