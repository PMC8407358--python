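# Methods

## Scope and data model

`neoburst` analyses multichannel neonatal EEG (channels × samples, µV, one
sampling rate, default 250 Hz) recorded after therapeutic hypothermia for
hypoxic-ischemic encephalopathy. Artifactual samples are marked in a shared
per-sample boolean mask rather than excised: cutting would compress the time
axis and bias the hour-scale spectral period estimate, whereas masking keeps
true timestamps and simply excludes flagged windows from statistics.
Burst events and cohorts are plain pandas DataFrames with documented column
schemas, so every intermediate is inspectable and serialisable as TSV.

EDF files are read through MNE; writing uses a minimal built-in EDF writer
(16-bit samples over a symmetric physical range, 1-s records). Quantisation
error is bounded by (physical range)/32767 — ~0.03 µV for a ±1000 µV range —
well below any threshold used here.

## Artifact criterion

Samples where any channel exceeds 500 µV in absolute value, padded by 0.5 s
per side, are masked. The amplitude criterion is the automatable core of
visual artifact review; topographic plausibility ("physiological voltage
field") cannot be decided from amplitude alone and is out of scope. Both
threshold and pad are parameters.

## Burst detection

The 8–30 Hz band is isolated with a 4th-order zero-phase Butterworth filter
(zero-phase preserves burst timing; note the response is ~3% down at 10 Hz,
near the 8 Hz corner — relevant when validating with near-edge test tones).
RMS amplitude is computed over sliding 400-ms windows with a 100-ms hop
(75% overlap, resolving the duration criterion to ±0.1 s; hop is
configurable, including hop = window for contiguous windows). Per channel,
the threshold is 1.5 × the standard deviation of its RMS series over the
whole recording, computed on artifact-free windows only. Maximal runs of
windows *strictly* above threshold spanning ≥0.5 s become events; runs
touching a masked window are discarded; events separated by a single
sub-threshold window are not merged (no merge rule is defined). A
numerically flat RMS series (e.g. a filtered constant) yields no events.

Normalised burst power is the time-domain mean of the squared band-passed
signal over [onset, offset], i.e. band power integrated over the burst
divided by its duration (µV²; A²/2 for a pure in-band tone of amplitude A).
The Morlet decomposition is *not* used for this quantity — the time-domain
integral is exact for the band definition and cross-checks against the
wavelet path within a few percent on narrowband bursts.

Because the threshold scales with the signal, detection is gain-invariant:
scaling a recording by c > 0 leaves the event set identical and multiplies
powers by c². This also means detection cannot be fooled by amplifier gain
differences between infants.

## Time–frequency maps

Bursts are characterised on a log-spaced 60-point grid over 0.2–40 Hz with
a cycle count linear in log-frequency from 3 (at 0.2 Hz) to 135 (at 40 Hz);
the exact original cycle parameterisation is not recoverable, so this
explicit schedule is the package's own documented choice. The 3-cycle
wavelet at 0.2 Hz spans ~24 s and the schedule peaks near 82 s around
0.5 Hz, so epochs are automatically cut wide enough to contain the longest
wavelet; bursts too close to the recording edges, or without 11 s of
unmasked pre-onset baseline, are skipped and counted.

Per burst, power is converted to dB as 10·log10(P) minus the per-frequency
mean of 10·log10(P) over the 11-s pre-onset baseline. Normalising in the
log domain (rather than dividing by the baseline mean of raw power) makes
each burst's baseline rows average to exactly 0 dB and cancels any static
gain; the two differ by a Jensen-inequality offset that would otherwise
leave a constant negative bias in the baseline. Maps are averaged across
bursts into a grand average per channel.

## Sleep-cycle periodicity

Burst powers are binned by onset into 60-s bins (resolving periods ≥0.25 h);
empty bins are filled by linear interpolation and flagged. The mean-removed
series is Fourier-transformed without tapering (a taper can be applied
upstream if desired); the highest-magnitude bin with period below 3.5 h and
above two bin widths is the sleep-cycle estimate. Estimates from recordings
with under 4.5 h of clean data are flagged unreliable — for such short
recordings the identified peak is driven almost entirely by recording
length. A diagnostic (`cycle_reliability_check`) correlates estimated
period/amplitude against recording duration and masked fraction across
recordings and flags dependence at p < .05.

"Time since last burst" is measured onset-to-previous-offset (elapsed
silence), with onset-to-onset as an option; the first burst per channel and
pairs spanning a masked interval are excluded. The headline number is the
mean of per-channel Pearson coefficients. The parasagittal channel C4 is
the default for the headline power series.

## Outcome statistics

Pearson r uses scipy with the two-sided t-test p; the 95% CI is a
percentile bootstrap over 1000 paired (case) resamples with a fixed seed
(degenerate resamples are dropped). Partial correlation removes the MRI
covariate from both variables by least squares and correlates the
residuals (identical to the closed-form r_xy·z); bootstrap resamples
triples. The ordinal 6-point MRI injury score is treated as numeric. A
correlation is significant only when p < .05 *and* the CI excludes zero.
No multiplicity correction is applied by default (Benjamini–Hochberg is
available but off), matching the analysis convention this package follows.

ROC analysis fixes the predictor direction (higher power ⇒ abnormal,
composite score < 85) rather than auto-orienting, which would inflate AUC
under the null. AUC is the trapezoidal area, identical to the Mann–Whitney
U statistic over n₁·n₀. The reported cutoff attains maximal sensitivity
and, among ties, maximal specificity.

The sample-size calculation uses the Fisher-z approximation
n = ⌈((z₁₋α/₂ + z_power)/atanh √R²)² + 3⌉, giving n = 28 for R² = 0.26,
80% power, α = .05; a simulation cross-check agrees within ±1.

## Synthetic data

The generator's defaults encode the descriptive statistics of the study
population this pipeline targets: bursts at 1/11.5 per second per channel
(one per 10–13 s), gamma-distributed durations with mean 1.7 s (shape 9,
floored at 0.6 s, spanning the 1.5–2.2 s range of observed medians), a
10 Hz carrier with raised-cosine 0.2-s on/off ramps (confining spectral
content to the 8–30 Hz band), and a 1.7-h sinusoidal sleep-cycle modulator
(the observed mean; range 0.7–3.3 h). Background is white Gaussian noise
low-passed at 40 Hz and rescaled to 10 µV SD per channel; burst amplitude
defaults to 50 µV (5× background) — background level and SNR are chosen for
detector testability, not physiological fidelity, since the analysis makes
no assumption about either.

Burst timing is an exponential onset-to-onset renewal process with a
refractory floor (previous duration + 0.2 s, keeping per-channel events
disjoint). With cycle depth d, candidate onsets are thinned with acceptance
probability 1 − d(1+m(t))/2, where m(t) ∈ [−1, 1] is the cycle phase:
bursts are *sparser* in the high-power phase, while their amplitude is
scaled by 1 + d·m(t) — together reproducing the tracé alternant signature
that long inter-burst intervals co-occur with high burst power (positive
interval–power correlation, ~0.2 at d = 0.5). Both thinning losses (cycle
and refractory dead time) are compensated in the proposal rate so the
realised mean rate equals the configured rate. Artifacts are Poisson in
time (per hour), 1–3 s long, rendered as >500 µV half-sine deflections on
all channels. All planted intervals are returned as a ground-truth table.

Cohorts draw a standardised latent power level z per infant; outcome
composites are mean 100, SD 15 with score = 100 − 15(√e·z + √c·z_mri −
√(1−e−c)·ε), so the population power–outcome correlation is exactly −√e
(higher power ⇒ lower score). The recorded power columns are a *linear*
map of z (mean 12, SD 2.5 µV², anchored to the 10.9–17.0 µV² scale of
duration-normalised burst power) — a nonlinear (e.g. lognormal) map would
attenuate the Pearson correlation below the configured effect size. The
MRI covariate is an ordinal 0–5 grade cut from its own latent; binning
attenuates its correlation with outcome relative to √c. Subscales are the
parent composite plus 5-point noise.

What the generator does **not** emulate: real neonatal background rhythms
and their state-dependent morphology, discontinuity/tracé alternant
waveforms, seizures, inter-channel burst co-occurrence, non-sinusoidal or
drifting sleep cycles, and non-Gaussian outcome distributions. Passing
tests therefore demonstrate that the pipeline recovers what it assumes —
planted bursts, planted periods, planted effect sizes — not that it would
perform identically on patient EEG.

## Problem sizes and numerical choices

Tests and the acceptance script use 30-min recordings for detector
validation (≈1400 planted bursts), 12-min recordings with sparse bursts for
time–frequency maps, 8-h event-level simulations for periodicity, and
2000/500-replicate simulations for power, type-I and permutation-null
calibration; these sizes give sampling error comfortably inside each
asserted tolerance. Ties at exactly the detection threshold end a run
("strictly above"); RMS uses a cumulative-sum formulation equal to the
naive computation to ~1e−12; bootstrap CIs use fixed seeds throughout, and
the whole pipeline is bit-reproducible for a fixed seed and config.

## Known limitations

- The amplitude-only artifact criterion cannot reject physiologically
  implausible but low-amplitude artifact (e.g. ECG bleed).
- The spectral period estimate inherits DFT bin granularity (an 8-h series
  resolves 1.7 h only to the nearest of 1.6/2.0 h); no interpolation or
  zero-padding is applied.
- Partial-correlation bootstrap resamples cases, not residuals.
- The EDF writer emits a fixed reference date and truncates trailing
  partial seconds.
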