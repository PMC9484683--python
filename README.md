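# epsckit

Automated detection and kinetic analysis of spontaneous excitatory
postsynaptic currents (spEPSCs) in patch-clamp time series.

## The problem

Spontaneous synaptic currents appear in voltage-clamp recordings as
irregular sequences of brief, negative-going (inward) deflections with
variable amplitude and kinetics, riding on noise and a slowly floating
baseline. Manual event picking is slow, fatiguing and biased; `epsckit`
provides fully automated detectors plus the machinery to compare them
quantitatively:

* **simple** — local-extrema threshold detector: a Blackman-Harris-filtered
  trace is scanned for local minima; the step from the preceding local
  maximum must exceed an amplitude threshold and contain a slope steeper
  than a slope threshold. Cannot locate event ends.
* **slope** — derivative-trigger detector: an event opens when the first
  derivative of the filtered trace falls below a negative threshold, the
  local minimum is the peak, and the event closes when the positive decay
  slope falls back below a positive threshold; events longer than a preset
  maximum duration are discarded. Event starts are refined by linearizing
  the steepest flank back to the pre-event baseline.
* **autoclassifier** — a machine-learning detector: an autoencoder
  (dense 128 → 1024 → 256 → 8-softmax encoder, mirrored decoder) learns a
  latent description of 128-sample windows (5.12 ms at 25 kHz); k-means
  (k = 7) on robust-scaled latents yields the *states* an event passes
  through as it transits the window; a small feed-forward classifier maps
  windows to states. Events are read off the per-time-step state sequence
  as stairs in two ordinal encodings (forward/reverse chronological order),
  gated by duration (0.8–10 ms) and a < 25 % noise-state proportion.
* **kudoh**, **muthmann** — re-implementations of two published reference
  detectors (multi-step threshold; MAD threshold on a Bessel-band-passed
  trace) for comparison.

Detector outputs are compared by optimal one-to-one event assignment on
peak times: the thresholded distance matrix

    C_ij = |a_i − b_j|  if |a_i − b_j| ≤ γ,   infeasible otherwise

is matched by a linear-assignment solver (maximum feasible cardinality,
then minimum total distance), giving missed-event rates, precision/recall
and F1 against ground truth. Per-event kinetics (duration, amplitude,
10–90 % rise time, single-exponential decay τ) and jointly normalized
kernel-density summaries complete the analysis.

A ground-truthed synthetic generator (Poisson event times, log-normal
amplitudes, biexponential waveforms `−A·k·(e^(−t/τ_d) − e^(−t/τ_r))`,
band-limited noise, sinusoidal baseline drift) makes the entire pipeline
testable without any recorded data.

## Worked example

```python
from epsckit import (SyntheticSpec, generate_trace, SlopeDetector,
                     SimpleThresholdDetector, precision_recall_f1,
                     missed_rate_matrix, measure_event_set)

trace, truth = generate_trace(SyntheticSpec(duration_s=30.0, seed=1))

slope = SlopeDetector(neg_slope_threshold=-2.2e4, pos_slope_threshold=2.2e3)
simple = SimpleThresholdDetector(amplitude_threshold=10.0, slope_threshold=1e4)
ev_slope, ev_simple = slope.detect(trace), simple.detect(trace)

for name, ev in [("slope", ev_slope), ("simple", ev_simple)]:
    s = precision_recall_f1(ev, truth.peak_s.copy(), gamma=2e-3)
    print(f"{name}: {s['n_detected']} events, precision {s['precision']:.3f}, "
          f"recall {s['recall']:.3f}")
print(missed_rate_matrix({"slope": ev_slope, "simple": ev_simple}, gamma=2e-3).round(3))
```

prints

```
slope: 271 events, precision 0.985, recall 0.971
simple: 269 events, precision 1.000, recall 0.978
        slope  simple
slope    0.00   0.022
simple   0.03   0.000
```

i.e. on 30 s of simulated recording (275 true events, ~20 pA mean
amplitude over ~1.5 pA noise) both threshold detectors find nearly all
events with almost no false positives, and each misses only 2–3 % of the
other's events under the γ = 2 ms optimal assignment. Kinetics per event
come from `measure_event_set(trace, ev_slope)` — here mean amplitude
21.1 pA, mean 10–90 % rise 0.47 ms, mean decay τ 2.2 ms, matching the
generator's settings.

The same workflow is available from the shell:

```
epsckit simulate --duration 30 --seed 1 --out sim/
epsckit detect sim/trace.csv --method slope --out det/
epsckit measure sim/trace.csv det/events.csv --out kin/
epsckit compare det/events.csv det2/events.csv --out cmp/
epsckit train sim/trace.csv --n-windows 5000 --epochs 20 --out model/
```

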