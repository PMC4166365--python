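# gammasnap

Models and analysis tools for **temporal-sequence to spatial-pattern
conversion by gamma-cycle snapshot modules**, motivated by olfaction: an
odor is encoded by *which* mitral cells emit a burst ("sharp event")
during *which* gamma cycle of a sniff, and a downstream network can decode
this sequence by dedicating one persistently active module to each gamma
cycle.

The package implements:

* **`gammasnap.ts_input`** — the gamma-discretized input generator:
  per-channel events at (jittered) gamma-cycle midpoints, firing-rate
  transients `Δr = P·Δt·δ(t − t_sp) − (r − r_base)Δt/τ_sp + noise`
  (P = 200 Hz, r_base = 20 Hz, τ_sp = 10 ms), and per-cycle binary
  activation patterns.
* **`gammasnap.binary`** — a generic decoder of intrinsically bistable
  binary units with hysteretic activation (`f = 1` above `u₊`, `0` below
  `u₋`, history-dependent between) and a threshold gradient across
  modules.
* **`gammasnap.spiking`** — a conductance-based decoder: two-compartment
  Hodgkin–Huxley excitatory cells whose dendritic bistability arises from
  voltage-dependent NMDA excitation (magnesium block) against
  GABA-B-activated inward-rectifier potassium (KIR) inhibition, primed
  module-to-module by feedforward input.  Includes the energy-landscape
  analysis of the stable dendritic voltages.
* **`gammasnap.metrics`** — the gamma modulation index
  `GMI = 1 − 12·mean((Φ − ½)²)`, the accuracy index
  `AI = 1 − (spurious + missed)/n_events`, and a parameter-sweep driver
  relating input discretization to decoding accuracy.
* **`gammasnap.ephys`** — the spike/LFP analysis chain for gamma phase
  locking of burst onsets (PSTH, sharp-event detection, zero-phase 40–80 Hz
  Butterworth filtering, instantaneous phase, circular mean
  `Z = N⁻¹Σe^{iθ}`, bootstrap), validated against a synthetic session
  generator with known injected locking.

See `docs/methods.md` for the model equations, parameter tables and
limitations.

## Worked example

Run the reference spiking-network simulation — three modules of 400 cells
decoding 100 events per 30 ms gamma cycle with zero onset jitter — and
score the final persistent pattern:

```sh
$ gammasnap simulate-spiking --seed 4 --out out/
AI=0.653 GMI=1.000 active per module=[102, 111, 9]
```

`GMI=1.000` says every input event sat exactly at its cycle midpoint.
The three numbers are the excitatory cells active in the last 50 ms of
each module: modules 1 and 2 hold ~100-cell snapshots of their cycles
(close to the 100 expected), module 3 latched only part of its cycle in
this realization, and `AI=0.653` summarizes the match between the final
pattern and the input assignment (1 = perfect; > 0.7 counts as a
successful decode; across seeds this configuration averages ≈ 0.75).
The run also writes the spike raster (`raster.csv`), the active/expected
sets (`active_sets.json`), a raster figure and a provenance record.

The same experiment degrades gracefully as the input loses its gamma
discretization — the relation quantified by the sweep:

```sh
gammasnap sweep --preset reduced --seeds 2 --seed 0 --out sweep_out/
```

which reports, per onset-jitter level, mean accuracy and the regression
of AI on measured GMI (positive slope: sharper gamma modulation, better
decoding).

The ephys chain round-trips on synthetic data:

```sh
$ gammasnap synth-session --seed 2 --kappa 5 --out sess/
$ gammasnap analyze-ephys --spikes sess/spikes.csv --lfp sess/lfp.csv --out eph/
|Z|=0.749 mean phase=-2.176 rad (20 trials)
```

The injected locking (von Mises κ = 5 at −2.3 rad) is recovered as a
concentrated phase distribution (|Z| = 0.75) at −2.18 rad.

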