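# Methods

This note documents the models and procedures implemented in `epsckit`, the
parameter choices that matter, and what the test suite does and does not
demonstrate.

## Signal model and preprocessing

A trace is a uniformly sampled single-channel current signal (pA); events
are inward, i.e. negative-going, and all amplitudes are reported as
positive magnitudes of the downward deflection.

The canonical internal sampling rate is 25 kHz — the rate at which the
autoclassifier's 128-sample window spans 5.12 ms. Traces at other rates
are resampled on ingestion (polyphase FIR resampling, so decimation is
anti-aliased). Preprocessing for the machine-learning path is:

1. **Baseline correction.** The trace is smoothed with a kernel ten times
   the length of the analysis window and the smoothed series subtracted.
   This removes baseline structure much slower than the analysis window
   while passing brief events. It is a linear operation; a brief event
   loses a small fraction of its amplitude (≈ 13 % for a 2 ms-decay event
   against the 128-sample analysis window), identically for all detectors.
2. **Unit scaling.** The corrected trace is affinely mapped to [0, 1].
   This presumes every trace contains at least one large event to anchor
   the scale; a pure-noise trace would be blown up to full range and its
   noise misclassified. This assumption is inherited by everything
   downstream and is the main data contract of the trained model.

Smoothing kernels are minimum 4-term Blackman-Harris windows rescaled to
unit sum (so smoothing preserves the DC level), applied with reflect
padding so output length equals input length and trace ends are not
amplitude-biased. The Blackman-Harris family is used for its very low
sidelobes — filtered extrema stay where the signal puts them. Widths are
stated in samples at the rate they are applied (21 for trace filtering,
17 for state-track filtering). Because the width of the trace filter was
originally stated at 50 kHz while the internal rate is 25 kHz, the width
is exposed as configuration; the default of 21 taps at 25 kHz was kept
because it suppresses band-limited recording noise (≈ 1 kHz) far better
than the 11-tap equivalent while still passing sub-millisecond rise
flanks.

## Threshold detectors

Both run on the filtered trace, with first derivatives estimated by
central differences and expressed in trace units per second.

**simple.** Local minima are paired with the nearest preceding local
maximum (falling back to the highest sample since the previous minimum on
perfectly flat stretches, where no strict maximum exists). An event is
reported when the max-to-min amplitude exceeds `amplitude_threshold` and
the steepest negative slope between them exceeds `slope_threshold`. Ends
are not determined. Each max/min bracket can produce at most one event.

**slope.** A sequential state machine: a negative trigger opens an event
when the derivative falls below `neg_slope_threshold` (< 0); the peak is
the local minimum at the derivative's zero crossing; after the peak the
closing trigger arms when the positive decay slope exceeds
`pos_slope_threshold` and fires when it falls back below it. Events whose
start-to-end span exceeds `max_duration_ms` (default 10 ms, the preset
that also excludes long inhibitory currents) are discarded, as are events
never closed before the trace ends (counted in the returned diagnostics).
A new event cannot open before the previous one closes.

**Event-start linearization.** Derivative triggers fire on the flank, not
at the onset. The start is therefore refined as the intersection of the
tangent at the step's inflection point (extremum of the first derivative)
with the horizontal line through the nearest preceding zero-slope point.
"Zero slope" is taken as |derivative| < 5 % of the trigger magnitude,
since exact zeros do not occur on noisy data; if no such point exists
within a lookback limit the trigger sample is used (logged). The
intersection generally does not lie on the signal; it marks the proper
start time and baseline value, and it is exact for an ideal
flat-then-ramp step.

Thresholds are deliberately *configuration, not constants*: the minimal
amplitude that separates a single-vesicle event from noise cannot be
estimated reliably and must be set per cell type. The defaults
(amplitude 10 pA, slope 1 × 10⁴ pA/s for simple; −2.2 × 10⁴ / +2.2 × 10³
pA/s for slope) were calibrated once against the synthetic generator's
default conditions by comparing the derivative statistics of noise-only
stretches with the analytic slope of the default event waveform; they are
not tuned per trace.

## Reference detectors

**kudoh** (multi-step threshold): per-step scan with a forward slope
trigger (slope measured across the local-mean halfwidth, since a
single-sample difference is noise-dominated), an onset search until the
signal departs the local baseline by `noise_level`, and a
forward-then-backward peak search comparing local means of halfwidth
`mean_halfwidth` (default 5 samples; the original description leaves this
open). The original multi-exponential kinetic fitting is intentionally
not reproduced. Peak localization degrades with noise, which the tests
document rather than bound.

**muthmann** (MAD threshold): 3-pole Bessel band-pass 0.1–2 kHz, noise
level estimated as the median absolute deviation (MAD) of the filtered
signal, events as negative excursions beyond `threshold_factor × MAD`
(default 4), grouped across gaps shorter than 1 ms, peak at the excursion
extremum. A floor of 6 % of the maximum filtered deflection guards
against the filter's own sidelobes being counted as events on
(near-)noiseless traces, where the MAD estimate collapses. The detector
is deliberately left as sensitive (and noise-prone) as its description:
it over-detects on band-limited noise, which is part of what the
comparison framework is meant to expose.

## The autoclassifier

**Autoencoder.** Dense encoder 128 → 1024 → 256 → 8 with relu hidden
layers and a softmax bottleneck (unregularized); dense decoder
8 → 1024 → 256 → 128 with a linear output. Hidden weights carry an L1
penalty of 5 × 10⁻⁶ to provoke sparse connectivity. Training: Adam
(initial rate 10⁻³), Huber loss, batch 32, with the learning rate reduced
by 0.2 after 10 epochs without improvement down to 10⁻⁶. The softmax
bottleneck makes the latent code a point on the 7-simplex — close to a
discrete state with room for interpolation, which is what the clustering
step assumes.

**Clustering.** Latents of a clustering sample are scaled by a robust
scaler (median removed, interquartile range divided; a zero-IQR dimension
passes through unscaled) and grouped by k-means with k = 7. Each
cluster's "common signal" is a Nadaraya-Watson kernel regression of its
member windows over the 128-step axis with Gaussian kernel width 2.0
time steps; per-cluster counts and member-vs-prototype RMS are recorded.

**State ordering.** The noise cluster is the one with the flattest
prototype (smallest peak-to-peak; ties broken by the larger count — the
noise state is the most frequent). The remaining six clusters are ordered
chronologically by the position of their prototype minimum, descending:
an event enters the analysis window at its trailing edge and ages toward
the leading edge, so "young" states have their minimum late in the
window. Exact positional ties are broken by latent-center norm (logged).
If every event-cluster prototype is flat the model cannot express events
and a degenerate-model error is raised.

**Classifier.** Feed-forward 8 → 64 → 64 → 64 → 7 with relu hidden
layers (L1 10⁻³, dropout 0.3) trained with softmax cross-entropy on the
cluster labels (stratified 80/20 split, Adam 10⁻³, batch 32, plateau
schedule as above). Hidden sizes are configurable; 64/64/64 is small
enough for CPU and ample for a 7-class map from 8 inputs.

**Detection.** Every window position of a preprocessed trace is
classified (stride 1 by default; a larger stride trades start/end
resolution — one sample per stride step — for speed). Labels are
re-encoded on two ordinal tracks: forward (event clusters at descending
chronological rank, noise = 0) and reverse (ascending rank). Both tracks
are filtered with a 17-tap Blackman-Harris kernel; a step is detected
where the filtered slope reaches 0.51 ordinal units per time step — large
enough that only the 6-rank jump at an event boundary (≈ 1.0 after
filtering) triggers, while the ±1 (and ±2) rank transitions inside the
stair (≲ 0.35) do not. The start step is read from the forward track, the
end step from the reverse track; each start is paired with the nearest
subsequent end and unpaired starts are dropped. Track indices are mapped
to trace coordinates by the window length (an event enters the window one
window-length before its onset appears at the track index), and events
are gated to durations within [0.8, 10] ms and a noise-state proportion
below 25 %. When the trace is available the reported peak is refined to
the trace minimum inside the event.

**Training core.** The networks are trained by a compact dense-network
engine written for this package (`epsckit.nn`): float32 numpy forward and
backward passes, Adam, Huber and softmax cross-entropy losses, inverted
dropout, L1 weight penalties and the reduce-on-plateau schedule. All
randomness (window sampling, weight initialization, k-means seeding,
splits, dropout masks) flows from a single pipeline seed, which makes
every trained model bit-reproducible.

## Event assignment and comparison

Two event sets are compared on peak times. Pairs farther apart than γ are
infeasible; the remaining pairs are matched one-to-one by a rectangular
linear-assignment solver, using a large finite surrogate cost for
infeasible pairs and discarding any surrogate assignment afterwards. This
realizes "keep assigning while both sides have assignable events"
(maximum feasible cardinality) with minimum total distance, and avoids
the failure mode where an unassignable event crowds out genuine matches.
The solver is verified against exhaustive enumeration for all set sizes
up to 6. γ defaults to 2 ms — within typical rise-time scales, so matched
peaks belong to the same physical event; missed rates are reported as the
fraction of a reference detector's events left unmatched.

## Event kinetics

Amplitude is the linearized start value minus the peak value (falling
back to the median of a 2 ms pre-event span when no start value exists).
The 10–90 % rise time interpolates the crossings of 10 % and 90 % of the
amplitude on the rising flank linearly between samples. Decay τ comes
from a single-exponential least-squares fit from peak to end, seeded by a
log-linear fit and refined nonlinearly; the fit RMS is reported as
quality. If a detector provides no end, one is imputed at peak + 4 fitted
decay constants (logged). Kernel-density summaries use Gaussian KDEs
(Scott's rule by default) jointly rescaled so per-detector areas are
proportional to set sizes and sum to 1; single-value groups receive a
minimum-bandwidth Gaussian spike instead of a degenerate KDE.

## Synthetic data: what it emulates and what it does not

The generator produces the statistical structure the detectors assume:
homogeneous Poisson event times (the standard model for spontaneous
release), log-normal peak amplitudes (strictly positive and right-skewed,
as empirical amplitude distributions are), biexponential waveforms with
per-event log-normal jitter on both time constants, white plus
band-limited Gaussian noise, and a slow sinusoidal baseline. Overlapping
events sum linearly, with no refractoriness.

Default conditions (chosen once as a realistic good-quality recording):
25 kHz sampling, 8 events/s, 20 pA mean amplitude (CV 0.3), τ_rise
0.4 ms, τ_decay 2 ms (kinetic jitter CV 0.25), noise 0.2 pA white plus
1.5 pA band-limited at 1 kHz — real acquisition chains low-pass filter at
the amplifier, so band-limited noise dominates — and a 5 pA, 10 s
baseline drift. Mean event amplitude is thus ≈ 13 noise standard
deviations. Training traces for the machine-learning path use 60
events/s so that a substantial fraction of random windows contains event
structure, mirroring training on event-rich recordings.

Not emulated: channel-level noise statistics and their complex time
correlations, electrode drift and seal instabilities, inhibitory (long)
events, multiplicative (amplitude-dependent) noise, and non-Poisson
burstiness. Passing tests therefore demonstrate algorithmic correctness
and the detectors' operating characteristics under the stated conditions
— not detection performance on any particular biological preparation,
where noise spectra and event-shape families differ.

## Problem sizes used in tests and the acceptance script

The machine-learning pipeline is exercised at a scaled-down size chosen
for single-CPU runs: 5 × 10³ training windows, 10³ validation windows,
20 autoencoder epochs and 30 classifier epochs (the full-scale defaults
are 5 × 10⁴ / 10⁴ / 100 / 100), trained on three 10 s event-dense traces
and evaluated on three held-out 8 s default-condition traces. Threshold
detectors are evaluated on five seeds of 60 s traces. At these sizes the
scaled-down pipeline reaches event-level F1 ≈ 0.85–0.9 against ground
truth at γ = 2 ms with classifier validation accuracy ≈ 96–98 %; larger
training budgets improve the state model.

## Known limitations

* The unit-scaling contract (every trace contains at least one large
  event) makes the autoclassifier unsuitable for near-silent traces
  without re-anchoring the scale.
* The state-track geometry ties the maximum event footprint to about
  three window lengths; much longer events (e.g. inhibitory currents)
  need a different window parametrization.
* The slope and simple detectors have no automatic threshold tuning by
  design; thresholds must be chosen per cell type.
* The kudoh and muthmann implementations are faithful-in-spirit
  re-implementations from published descriptions, not wrappers of the
  original code; parameters those descriptions leave open are exposed
  with documented defaults.
* Decay fitting is single-exponential; events with genuinely
  multi-exponential decay report an effective τ.
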