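# Methods

`gammasnap` models how a temporal sequence of neural activity, discretized
by gamma-frequency oscillations, can be converted into a persistent spatial
pattern by a bank of working-memory-like modules, and provides the analysis
chain that established the empirical premise — that mitral-cell "sharp
events" in the olfactory bulb are locked to a preferred gamma phase.  This
note documents the models, the substituted constants, the numerical choices
and the known limitations.

## The decoding problem

A sending network ("TS", temporal sequence) emits one brief event per
channel; each event targets the middle of one gamma cycle (30 ms) with
Gaussian onset jitter.  A receiving network ("SP", spatial pattern) of
three modules must end the sequence with module *m* persistently active in
exactly the cells whose channels fired during cycle *m*.  Two
implementations are provided.

## Binary bistable-unit model (`gammasnap.binary`)

Each unit integrates its input `u` with `tau du/dt = -u + sum W f - Delta`
(`tau = 20` model time units) and carries a hysteretic activation: `f`
switches to 1 above `u+ = 1`, to 0 below `u- = -10`, and is otherwise
history-dependent.  Connectivity is random and sparse: 100 TS channels onto
3×300 units (p = 0.01, weight 2), within-module excitation (p = 0.01,
weight 0.1) and inhibition (p = 0.30, weight −1.5), and feedforward
excitation to the next module only (p = 0.01, weight 4).  Module
excitability offsets are (0.5, 2.5, 4.5): the threshold gradient that
makes module *m* need priming from modules < *m*.  A gamma cycle is 16
time units, TS input on during the first 8; integration is classic RK4 at
`dt = 0.2` with activations updated after each full step (hysteresis is a
discrete device and is kept out of the stage evaluations); ties at the
thresholds keep the previous state; units start at the no-input fixed
point `u(0) = -Delta`, `f(0) = 0`.

**Sparseness of the reference parameterization.**  With these constants a
unit sees Poisson(0.3) active TS inputs per cycle and must accumulate at
least three coincident inputs to cross `u+` within the 8-unit input
half-cycle, so a typical run activates only a handful of units per module.
Two consequences, verified by the tests: activation before a module's
designated cycle essentially never happens (the threshold gradient needs
≥6 coincident inputs to be violated), and activations persist to the end
of the run (inhibition never drives `u` below `u-`).  However, the
mechanism that should make a module ignore input *after* its cycle —
accumulated feedback inhibition from its own active population — needs a
much denser population than a handful of units: a late candidate escapes
all inhibitory connections from 4 active units with probability
0.7⁴ ≈ 24%.  Consequently the final sets of modules 1–2 are *not* strictly
invariant to the third-cycle input: one to four marginal units differ
between third-cycle patterns in most random realizations.  Starting units
from `u(0) = 0` densifies module 1 enough to lock it but then lets
three-input coincidences activate later modules *before* their cycle; no
initial condition reconciles both properties under these constants.  The
corresponding invariance test is left failing rather than weakened.

## Conductance-based spiking model (`gammasnap.spiking`)

Three identical modules of 320 two-compartment excitatory cells and 80
single-compartment interneurons.  Excitatory dendrites carry the synaptic
machinery; somas carry Na⁺/K⁺ spike currents; a coupling conductance
(`g_c = 0.1 mS/cm²`, area split 0.5/0.5) joins them.  Bistability arises
from two voltage-dependent synaptic currents with opposite voltage
preferences:

* **NMDA** (feedforward from the previous module, recurrent within the
  module, and from the 320-channel start signal onto module 1), gated by
  the standard sigmoidal magnesium block `1/(1 + exp(-0.062 V)[Mg]/3.57)`
  with [Mg] = 1 mM — conducts when depolarized;
* **GABA-B-activated KIR** from the module's interneurons, with inward
  rectification `1/(1 + exp(0.1 (V - E + 10)))`, E = −90 mV — conducts
  when hyperpolarized.

The quasi-static energy landscape of a dendrite (`energy_landscape`) is
the integral of the net outward current over voltage with the synaptic
activations frozen; its minima are the stable voltages.  A module passes
through the three stages the landscape makes explicit: *unprimed* (single
resting well — TS input produces at most transient firing), *primed*
(NMDA active, GABA-B low — the same TS input removes the resting well and
the cell switches to the depolarized well, where the rectified KIR no
longer reaches it), and *locked* (GABA-B/KIR built up — the resting well
is deep and the TS input cannot remove it).

### Synaptic kinetics

Activation variables decay exponentially and jump by `alpha (1 - s)` per
presynaptic spike: AMPA `tau = 2 ms, alpha = 0.9`; NMDA
`tau = 100 ms, alpha = 0.5` with an additional conductance rise constant
(0.5 ms; the field exposes slower dual-exponential kinetics); GABA-A
`tau = 6 ms, alpha = 0.9` (E = −70 mV).  The TS input is a linearized
conductance `s = 0.00175 r` per channel (the slope of the closed-form
steady-state activation `s(r)` below 150 Hz), `g = 0.4 mS/cm²` onto the
same-index excitatory cell of every module and `0.2/N_P` onto every
interneuron.

**GABA-B cascade.**  GABA-B/KIR gating is modeled as a cooperative,
use-dependent G-protein cascade: each interneuron spike increments a
receptor gate by `alpha_B · exp(-ISI/tau_f) · (1 - x)` (`alpha_B = 0.45`,
`tau_f = 5 ms`; the facilitation factor captures the pooled transmitter
needed to reach extrasynaptic GABA-B receptors, so only high-frequency
firing recruits the cascade), `x` decays with 60 ms, and the G-protein
level relaxes toward the Hill function `x⁴/(x⁴ + K⁴)` (`K = 0.186`) with
5 ms.  The result is the slow sigmoidal rise of the KIR conductance over
tens of milliseconds that follows *sustained fast* interneuron firing and
ignores sparse spiking.  This shape is what lets the strongly driven
module-1 interneurons (start signal, ≈300 Hz) lock their module within one
cycle while the weakly driven interneurons of a not-yet-active module
(feedforward only, ≈100 Hz) leave it flippable during its own cycle.

**KIR pool.**  The per-synapse KIR current keeps the printed form
`g (0.05 + 0.95 Σs)(V−E)/(1+exp(0.1(V−E+10)))`.  Summed over the module,
the 5% constitutive share is applied to a pool of 142.5 synapse
equivalents — a substituted constant that sets the resting-state defense
against the sustained start-signal drive.

### Substituted compartment constants

The spike-generating and passive machinery is this package's own
parameterization (every constant is a `SpikingParams` field):
Wang-Buzsáki-style Na/K kinetics (soma: `g_Na = 100`, `g_K = 40`,
temperature factor 1.0; interneuron: `g_Na = 45`, `g_K = 18`, factor 5),
somatic leak `0.3 mS/cm²` at −70 mV, dendritic leak `0.1 mS/cm²` at
−70 mV, interneuron leak `0.3` at −68 mV, membrane current noise
2.5 µA/cm²·√ms (Euler–Maruyama; it also desynchronizes the otherwise
identical cells of a module), spike detection at −20 mV somatic upward
crossings with a 1 ms refractory period.  Integration is forward Euler at
`dt = 0.025 ms`; a voltage magnitude above 200 mV aborts the run with a
diagnostic.

The excitatory maximal conductances default to `g_NMDA,EE = 82/(20·N_P)`
and `g_AMPA = g_NMDA/4` — members of the sweep grid rather than its upper
end — together with `g_GABA_A = 2.5/(10·N_I)` and
`g_GABA_B = 1300/(10·N_I)`.  At the grid-top NMDA value the start signal's
pooled conductance (all 320 channels at ~100 Hz, roughly three times the
feedforward pool of ~100 active cells) removes the resting well of every
module-1 cell before the GABA-B lock can form, so the whole module
ignites; the mid-range value balances module-1 stability against the
feedforward flip margin of modules 2–3.

### Reliability

The decoding operating point is narrow, as in the full-scale experiment
(only a few percent of the sweep's parameter sets ever succeed).  In the
reference configuration (zero onset jitter, 100 events per cycle, 150 ms)
the accuracy index over independent random realizations is ≈ 0.75 ± 0.15:
most runs exceed the 0.7 success threshold, occasional realizations fail
the module-1→2 handoff and land near 0.3–0.6.  The residual variance is
dynamical — the collective flip of a module is a noise-triggered avalanche
whose timing jitters by several milliseconds — and is reported rather than
hidden.

### Timing structure

The simulation lasts 150 ms: three 30 ms gamma cycles plus a 60 ms hold,
so the 50 ms readout window (cells with ≥2 spikes are "active") lies after
the three decoded cycles.  TS events sit at cycle midpoints (15, 45,
75 ms; channels beyond 3·N_prf target later cycles); the start signal
fires each of its 320 channels first at U(15, 30) ms and every 10 ms
thereafter.

## Indices and sweep (`gammasnap.metrics`)

`GMI = 1 − 12·mean((Φ−0.5)²)` on onset phases Φ ∈ [0,1): 1 for all-midpoint
events, 0 for uniform phases.  The literal variance-normalized form
reaches −2 (not −1) at the cycle-edge extreme; an alternative
standard-deviation normalization is available behind `method="sd"`.
`AI = 1 − (spurious actives + misses)/n_events` against the cycle-specific
assignment.  The sweep driver runs one simulation per grid point and seed
over five axes (excitatory NMDA, GABA-A, channels per cycle, GABA-B, onset
jitter), records measured GMI (from realized onsets) and AI, and
summarizes success counts, per-jitter means and the regression of AI on
GMI with the reporting filter that keeps only parameter sets with at least
one success.  The full grid has 29,568 points; the `reduced` preset (48
points: two grid values per axis around the reference configuration ×
jitter {0, 4.5, 12} ms) exists because the success pocket is small and a
subsample spanning the full axes contains no successful set, leaving the
trend unmeasurable.

## Ephys chain and synthetic sessions (`gammasnap.ephys`)

The chain implements: 10 ms-bin trial-averaged PSTH; sharp-event detection
at ≥4.5 baseline SD above the 2 s pre-odor baseline (SD floored at 0.1 Hz
for silent synthetic baselines); per-trial burst onset as the spike
preceding the first inter-spike interval below `1.5/maxFR` within
[peak−2/maxFR, peak+4/maxFR]; zero-phase 4-pole Butterworth 40–80 Hz
filtering (`sosfiltfilt`); instantaneous phase
`atan2(S'(t)/σ_S', S(t)/σ_S)` with the normalizations computed over the
event window (the two-argument arctangent covers the full circle; phase 0
sits at a positive LFP peak and advances as −ωt); the complex circular
mean `Z = N⁻¹ Σ exp(iθ)` (an axial doubled-angle variant is available);
and a 10,000-replicate bootstrap of the population mean phase with
significance measured as the fraction of replicate means outside ±π/4 of
the original mean.

The synthetic session generator injects ground truth: per-trial LFP =
unit-amplitude 60 Hz sinusoid with random starting phase plus white noise
(SD 0.5); spikes = 4 Hz Poisson background plus one five-spike 200 Hz
burst whose first spike is placed at a von Mises(μ, κ) gamma phase in a
cycle near the nominal event time, with a trial-to-trial latency jitter of
SD one gamma cycle.  The latency jitter matters: real sharp-event
latencies vary by more than a gamma period, which broadens the PSTH peak
and hence the printed onset-search window; without it the window is
narrower than the onset spread and the chain truncates early onsets.
What passing tests show: the chain recovers an injected population phase
to ±0.3 rad and orders locking strengths by κ; they do not certify
performance on real recordings, whose LFP is nonstationary and broadband
and whose response bursts are far less stereotyped.

## Configuration and provenance (`gammasnap.config`, `gammasnap.cli`)

All module parameters live in a validated `RunConfig` (YAML/JSON/TOML;
unknown keys rejected).  Each CLI run derives all randomness from one
master seed through `numpy.random.SeedSequence` spawning, and writes a
provenance JSON with the effective configuration, seed, package version,
runtime and SHA-256 digests of every output, so identical config + seed
reproduce bit-identical outputs.

## Problem sizes used by the test suite

The suite runs the full-size spiking network (1,200 cells) for single
150 ms trials, the 48-point reduced sweep at two seeds (96 simulations,
~4 minutes), 20-seed batteries of the binary model, and 100 null ephys
populations of 12 sessions each with 2,000-replicate bootstraps; these
sizes keep the whole suite within a few minutes of CPU time while leaving
every statistical check adequately powered.

## Known limitations

* The spiking model's decoding is a knife-edge collective phenomenon;
  a minority of random realizations fail the module handoff (see
  Reliability above).
* The binary model's after-cycle lock is too weak at the sparse reference
  activation level; the corresponding invariance test fails by design
  honesty rather than being relaxed.
* Voltage traces are not comparable to any particular reference
  implementation — the acceptance surface is behavioral (bistability,
  locking, decoding accuracy), not trace equality.
* The ephys chain is validated on stationary synthetic sessions only; the
  population-level numbers from real recordings (218 unit-odor pairs) are
  not reproducible here because those recordings are not deposited.
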