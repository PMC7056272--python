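# Methods

This note documents the models implemented in `ephyskit`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
numerical choices that matter for reproducing results.

## Spike-wave discharge detection

### Signal model

An SWD is modeled as a rhythmic 3–6 Hz discharge of alternating sharp spikes
and slow waves, 1–2 s long (rarely > 4 s), appearing simultaneously on all
EEG channels. Detection makes three assumptions: (i) discharges raise epoch
RMS well above background; (ii) the sharp spikes add measurable power in the
100–300 Hz band relative to 0.5–80 Hz (the FBR feature); (iii) spikes are
large, brief transients separable from background by a robust amplitude
threshold.

### Stages and defaults

| stage | parameter | default | rationale |
|---|---|---|---|
| band-pass | cutoffs, order | 0.5–400 Hz, order 3 | preserves spike sharpness and slow waves; zero-phase (forward–backward) so peak latencies are unbiased — duration is defined peak-to-peak. The effective magnitude is the squared one-pass response. |
| epoching | epoch length | 250 ms | short enough to localize 1–2 s events, long enough for a stable spectrum (1250 samples at 5 kHz, 4 Hz resolution) |
| spike operator | k, min separation | 5 robust SDs, 40 ms | robust (MAD-based) scaling adapts to per-animal amplitude; 40 ms is below the shortest 3–6 Hz cycle spacing |
| thresholds | rms, FBR, spike density | 99th pct, 95th pct, ≥ 1 | percentiles of the recording's own feature distributions self-calibrate across animals and noise levels; explicit values can be supplied. Spike density ≥ 1 (not 2) because a 3-Hz discharge spaces spikes 333 ms apart — a 250-ms epoch can never hold two. |
| candidate rule | channel fusion | any EEG channel passes all three features | discharges are generalized but amplitudes vary per channel |
| episode merge | max gap | 1 epoch (250 ms) | discharges span several epochs; borderline epochs inside an event may fail a threshold |
| peak measurement | span margin | ±2 epochs | duration is first-to-last spike peak; weak events may flag only one epoch while their peaks extend beyond it. Inside a flagged span, peaks are accepted above max(3.5 robust SDs, 0.5 × span extremum) — locating peaks in a known event is a different problem from rejecting noise, and the 0.5× rule keeps slow waves (≈ 0.4× the spike) excluded. Episodes with < 2 peaks are discarded. |
| spike rate | — | (n_peaks − 1) / duration | the fence-post-correct cycle frequency; n/duration overestimates by one part in n_peaks−1 (4.67 Hz instead of 4.0 for a 7-peak, 1.5-s event) |
| clusters | size, gap | ≥ 5 episodes, ≤ 60 s (inclusive), offset→onset | definition of a discharge cluster |

The per-hour rate profile bins episode onsets by wall-clock hour of day and
divides by the coverage (hours of recording falling in that hour-of-day), so
`sum(mean_count × hours_covered)` always equals the episode count; hours
with zero coverage are reported missing.

### Candidate classifier

A compact numpy-implemented 1-D CNN refines candidates. The first layer
convolves 32 filters over non-overlapping 10-ms windows of the 3-channel
segment (kernel = stride = 10 ms of samples); two further two-conv blocks
(64, 128 filters, kernel 3, stride 1, same padding) each end in a 5× max
pool; global average pooling, 50% dropout and one sigmoid unit produce the
SWD probability. Segments are 1.25 s: 6250 samples → 125 steps after the
first layer → 25 → 5 → 1 after the three pools, and the window covers a
typical discharge. Training minimizes binary cross entropy with Adadelta
(ρ = 0.95), and stops when validation loss has not improved for 3
iterations (epochs); the best-validation weights are restored. Segments are
standardized per channel (zero mean, unit SD) so the classifier judges
morphology, not amplitude. The classifier partitions candidates by a
probability threshold (default 0.5) and can only remove candidates — the
threshold stage bounds what can ever be reported.

## Miniature-PSC detection (scaled template)

Sweeps acquired above 4 kHz are first low-pass filtered at 2 kHz
(zero-phase Butterworth, order 4). A biexponential template
w(t) ∝ (1 − e^(−t/τ_rise)) · e^(−t/τ_decay), preceded by a baseline of
zeros and scaled so its extremum equals the template amplitude, is slid
along each sweep. At each offset the trace is fit as scale·w + offset in
closed form; the detection criterion is scale ÷ residual standard error
√(SSE/(K−1)) — a ratio invariant to additive DC shifts and to rescaling the
trace. Local criterion maxima above the threshold (default 3.5, the
conventional operating point for this method), separated by at least the
template rise time, are events.

Per event: onset at the criterion peak plus the template baseline; local
baseline from the pre-onset baseline window; amplitude measured at the peak
found within ±1 ms of the template-predicted peak position (averaged
±0.3 ms) — restricting the search window avoids the upward bias of taking
the maximum of noise over the whole event extent; decay τ from a
log-linear fit from the peak down to 5% of the amplitude; charge by
trapezoidal integration from onset to the fitted 5%-of-peak time, capped at
5× the template decay. At 2 pA recording noise the detection floor is
≈ 8.6 pA equivalent amplitude (see Limitations).

## Quantal subtraction

With window means A (amplitude, charge, or decay τ) and frequencies f
(count ÷ window duration ÷ sweeps),

A_quantal = (A_light·f_light − A_baseline·f_baseline) / (f_light − f_baseline).

Light-window events are a rate-weighted mixture of background minis and
minis from the targeted class; the subtraction removes the background
contribution exactly for means of additive per-event quantities (amplitude,
charge). Decay τ is *not* additive over mixtures, so the same formula is an
approximation for τ; estimates are flagged when f_baseline/f_light > 0.5,
where it degrades. When f_baseline = 0 the estimator reduces to the sample
mean of light-window events, exactly. The mean quantal waveform is computed
by the same subtraction applied to the average event snippets of the two
windows.

QC: the rate increase is tested with the exact conditional binomial test of
the light count against the exposure fraction — the standard exact Poisson
two-sample rate-ratio test, one-sided at α = 0.05 — and the evoked yield
(light count − baseline count) must reach 150. The 150-event rule reflects
the sampling error of a mean: at amplitude CV 0.6, the mean of 150 events
has SE 0.6/√150 ≈ 4.9%, so |error| < 10% with probability ≈ 96%. The test
suite verifies this estimator-level property directly.

## Unitary IPSC analysis

Sweeps aligned to the 6-pulse, 10-Hz train are averaged. Baseline SD is
taken over the 50 ms of the average trace preceding the first pulse. Pulse
amplitudes are the extremal deflection (polarity fixed by pulse 1) of the
average trace, smoothed with a 1-ms moving average, within 15 ms of each
pulse, relative to a 2-ms pre-pulse local baseline; the smoothing stops the
measurement from chasing single-sample noise maxima, which would otherwise
call a substantial fraction of pure-noise pairs connected. A pair is
connected when the first-pulse amplitude ≥ 3 × baseline SD (inclusive).
Normalized train amplitudes (pulse k ÷ pulse 1) quantify depression.
`connectivity_summary` reports rates and (1 − rate_b/rate_a) × 100, rounded
to the nearest percent, matching how such reductions are conventionally
reported.

## Synthetic data

The generators are phenomenological; they emulate the statistical structure
the analyses rely on, not biophysics.

**EEG/EMG**: per-channel pink (1/f) background with an amplitude rolloff of
f^−2.5 above a 60-Hz knee — intracranial EEG falls steeply above the gamma
band, and without that rolloff the 100–300 Hz band carries so much
background that the FBR feature cannot separate discharges from noise.
NREM segments get a 1–4 Hz delta boost, awake/REM a 6–9 Hz theta component
(only so state stratification is exercisable). SWD cycles are 10-ms
triangular spikes carrying a small 200-Hz Gaussian-windowed ripple (the
fast component of epileptiform spikes), followed by an opposite-polarity
slow wave at 0.4× the spike, at 4–8× background RMS on all EEG channels
with ±20% per-channel jitter. Event times are Poisson; durations uniform
1–2 s with a small fraction drawn 4–6 s; an optional cluster of ≥ 5
episodes with bounded gaps can be injected. Myoclonic jerks are 50–200 ms
rectified EMG noise bursts preceded (configurable lag, default 15 ms) by an
EEG spike. Defaults (20 SWDs/hr, 30 µV background RMS, 5 kHz, 3 EEG + 1 EMG
channels) represent a seizure-dense recording at the stated acquisition
settings.

**Patch sweeps**: Poisson event times in a 10-s baseline and a 10-s light
window per sweep (defaults 1 vs 2 Hz, 15 sweeps), lognormal amplitudes
(mean 20 pA, CV 0.6 — typical for cortical mIPSCs), biexponential kernel
(rise 0.6 ms, decay 10 ms), a tonic current that peaks at light onset and
decays linearly to zero across the light window (mirroring a ramped-down
photostimulus), and Gaussian noise (SD 2 pA) at 10 kHz.

**uIPSC sweeps**: a 6-pulse 10-Hz train with per-pulse depression scale
factors (default 1, 0.8, 0.7, 0.6, 0.55, 0.5), 20% sweep-to-sweep amplitude
CV, white baseline noise; unconnected pairs are noise only.

What passing tests on these data do *not* show: robustness to movement and
chewing artifacts, electrode drift, state-dependent background
nonstationarity beyond the coarse delta/theta model, overlapping mini
events' deconvolution, or series-resistance errors. Those failure modes
require real recordings.

## Problem sizes

Tests run the EEG chain on one hour of synthetic recording at 5 kHz
(~20 discharges), train the classifier on 400 segments, and measure the
quantal chain over 500 seeded cells of 15 sweeps each; the acceptance
script uses the same sizes. These are the scales at which the statistical
checks (recall/precision ≥ 0.9, estimator bias < 2%, sample-size
probabilities) are stable from run to run.

## Known limitations

* **Detection-floor bias of the full quantal chain.** Threshold detection
  cannot see the smallest minis: at criterion 3.5 and 2 pA noise
  (≈ 1.23 pA after the 2-kHz low-pass) the floor is ≈ 8.6 pA, which at
  lognormal CV 0.6 around 20 pA hides the smallest ≈ 11% of events in both
  windows. The subtraction then converges to the truncated mean, ≈ +8.5%
  above the true mean, and baseline events at half the light rate roughly
  double the estimator variance (conditional SD ≈ 8.5% at 150 evoked
  events). Consequently the probability that the *complete* chain lands
  within 10% of the true quantal amplitude at ~150 evoked events is ≈ 53%
  (500-seed simulation), even though the estimation step proper — the mean
  of 150 events — is within 10% in ≈ 96% of runs. The 150-event QC rule
  should therefore be read as controlling sampling error relative to the
  *detectable* event population; comparisons between conditions with the
  same detection settings are unaffected, but absolute quantal amplitudes
  are biased upward by the floor. Lowering the criterion or the noise
  shifts the floor accordingly.
* Decay-τ subtraction is approximate for mixtures (flagged, see above).
* The SWD detector's percentile thresholds assume discharges are rare
  (≲ 1% of epochs); in recordings dominated by near-continuous discharge
  activity, explicit thresholds should be supplied instead.
* The EDF writer quantizes to 16 bits over each channel's observed range
  (≤ 0.01% of range per step); round-trips are exact to one quantization
  step but not bit-identical.
* The classifier is trained per dataset; no pretrained weights ship with
  the package, and the pipeline runs threshold-only when no model is given.
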