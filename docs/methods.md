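# Methods

`bulbarvoice` implements an automatic acoustic-analysis pipeline for
detecting bulbar involvement in amyotrophic lateral sclerosis (ALS) from
connected-speech recordings, and for staging patients into early (ALS-E)
and late (ALS-L) bulbar severity strata. The clinical recordings that
motivated the pipeline are access-restricted, so the package ships a
first-class synthetic-data module that emulates both the audio level and
the feature level of such a study; every quantitative claim in the test
suite is made against synthetic material with known ground truth.

## Recording model and preprocessing

Recordings are mono PCM WAV, conventionally 44.1 kHz / 16-bit readings of a
standard ~99-word passage. Preprocessing applies Boll-style spectral
subtraction: short-time Fourier analysis with 0.025 s Hann windows at 50%
overlap; the noise magnitude spectrum is estimated as the mean |STFT| over
a noise-only interval of at least 0.25 s (by default the first 0.25 s of
the recording, matching the assumption of a silent lead-in); the estimate
is smoothed with a 40 Hz-wide moving average over frequency, and twice the
smoothed noise magnitude is subtracted from each frame magnitude inside the
80 Hz - 10 kHz suppression band, floored at 2% of the noise magnitude, with
input phase reused for overlap-add reconstruction.

The oversubtraction factor of 2 is part of Boll's original method: plain
mean-magnitude subtraction leaves the upper tail of the Rayleigh-distributed
noise magnitudes and removes only ~3-6 dB of noise power, whereas
oversubtraction plus the 2% floor removes enough that a tone corrupted at
10 dB SNR comes back above 20 dB (measured against the stored clean
component). One consequence of the fixed 10 kHz suppression ceiling is that
broadband corruption of 44.1 kHz audio can never be attenuated by more than
~3.5 dB, because over half the noise power lies above 10 kHz; denoising
fixtures in the tests are therefore synthesized at 16 kHz, where the band
covers the full bandwidth. This is a fixture choice, not an algorithm
setting.

### Quality control

Two gates reproduce the screening protocol exactly: estimated SNR must
exceed 30 dB and fewer than 1% of samples may be clipped (|x| at or above
99.9% of full scale). Both thresholds are strict: SNR of exactly 30.0 dB
and clipping of exactly 0.0100 fail. Gating happens after noise reduction;
the pre-reduction SNR is recorded alongside.

The SNR estimator frames the signal at 10 ms, then splits frames into
active and silent at the geometric midpoint between the 95th- and
10th-percentile frame powers (never below -25 dB relative to the 95th
percentile). A bimodal midpoint is used instead of a fixed relative
threshold because the silence floor of a 20 dB-SNR recording sits at
-20 dB relative to speech — above any fixed -25 dB cut — and would
otherwise be classified as active. Recordings whose frame powers show less
than 6 dB of contrast (unbroken stationary noise, or unbroken speech) are
flagged indeterminate, which fails the gate with its own reason. The
estimate is capped at +60 dB, the value returned for digitally silent
floors.

## The 53-feature acoustic set

The feature inventory is data, not code: a versioned JSON manifest fixes
names, categories and column order (5 jitter + 6 shimmer + 5 harmonicity +
7 F0 + 7 intensity + 2 zero-crossing + 21 timing/rate = 53). Swapping the
manifest changes the extracted set, the generator's columns, and every
exported table without touching code. The composition reconstructs a
proprietary feature list from its published category inventory; "ac" and
"cc" are taken to be the mean frame autocorrelation at the pitch lag and
the mean cross-correlation of successive glottal cycles.

* **Pitch** — normalized autocorrelation per 40 ms frame (10 ms hop),
  search range 75-500 Hz, parabolic refinement of the peak, voicing
  threshold r >= 0.45, and a 0.02-per-octave lag cost to break
  period-multiple ties. Tracking error on synthetic vowels is below 1%
  across 100-300 Hz.
* **Pulses** — glottal-cycle marks at waveform peaks spaced by the tracked
  period, with parabolic sub-sample refinement of both time and amplitude.
  Without sub-sample refinement, sample-grid quantization alone would fake
  ~0.1-0.3% jitter at 44.1 kHz; with it, a perfectly periodic fixture
  measures ~0.003% jitter and ~0.07% shimmer. At 16 kHz the shimmer
  measurement floor rises to ~0.2%, which is why phonatory precision
  fixtures use the clinical 44.1 kHz rate.
* **Jitter/shimmer** — the standard perturbation quotients (local,
  absolute, rap, ppq5, ddp; local dB, apq3/5/11, dda), computed within
  contiguous voiced runs only. The identities ddp = 3·rap and dda = 3·apq3
  hold to machine precision and are asserted against direct formula
  evaluation.
* **Harmonicity** — per voiced frame r at the pitch lag gives
  HNR = 10·log10(r/(1-r)) capped at +-60 dB; ac/cc/noise-to-harmonics as
  above. On synthetic voices the measured mean HNR tracks the construction
  SNR within ~0.1 dB at 10 and 20 dB.
* **Intensity** — frame RMS in dB re full scale over speech-active frames;
  mean, median, min, max, range, variance, SD.
* **Zero-crossing rate** — sign changes per sample, counted over every
  sample gap and binned into 10 ms frames so crossings straddling frame
  boundaries are not lost (with aligned frames the naive per-frame count
  loses up to 30%).
* **Timing/rate** — energy-based speech/pause segmentation (10 ms frames,
  -25 dB relative threshold, minimum pause 0.15 s; this fixed relative
  threshold is valid here because feature extraction only sees QC-passed,
  >30 dB material). Pause classes: short 0.15-0.5 s, medium 0.5-1.0 s,
  long > 1.0 s. Syllable nuclei are intensity-contour peaks of >= 2 dB
  prominence inside speech. Speech rate = syllables per second of total
  time; articulation rate = syllables per second of speech time. Word-unit
  durations are speech-chunk durations standing in for words (no transcript
  alignment); the remaining timing features are pause/segment counts and
  duration statistics.

Features that cannot be measured (perturbation quotients on unvoiced audio,
intensity of silence) are NaN, flagged per feature, and imputed downstream
with training-split medians.

## Statistical model

Each binary contrast (control vs all ALS; control vs ALS-E; ALS-E vs
ALS-L, with ALS-E defined as bulbar subscale score >= 11 of 12) is fit
with Bayesian logistic regression:

    alpha ~ Normal(0, 1)
    beta_k ~ Laplace(0, 0.5),  k = 1..J   (Bayesian LASSO)
    y_i ~ Bernoulli(inverse_logit(alpha + x_i . beta))

Class 1 is always the less-impaired group, so a positive coefficient means
the less-impaired group has the higher feature value. The Laplace scale
0.5 is the width parameter of the double-exponential prior; on identical
data it concentrates markedly more posterior-median coefficients near zero
than a Normal(0, 1) prior (10/10 simulation seeds in the acceptance run),
which is the point of the LASSO construction: uninformative features are
pushed toward zero so the surviving coefficients are interpretable.

### Sampling

The posterior is log-concave (Bernoulli likelihood through the logistic
link plus log-concave priors), so it is sampled with Hamiltonian Monte
Carlo written in-package: analytic gradients (the Laplace prior contributes
its subgradient), a diagonal mass matrix initialized from the Fisher
information at the L1-regularized MAP (scikit-learn, C = 0.5 matching the
prior), one Stan-style warmup window that re-estimates the mass from
warmup-draw variances, dual-averaged step size targeting 0.8 acceptance,
and jittered trajectory lengths of 12-24 leapfrog steps. Defaults are 4
chains x 500 warmup + 500 kept iterations, all chains advanced in lock-step
through batched matrix products. Convergence is gated at rank-normalized
split-R-hat < 1.01 over all parameters (arviz); a failing fit is rerun once
with doubled length and otherwise excluded from its fold with the failure
recorded. On a fixed dataset the posterior medians agree with an
independent Gibbs implementation of the same model to ~0.03-0.04.

### Evaluation protocol

Ten class-stratified pseudorandom 50/50 train/test splits per contrast
(both classes guaranteed in both halves; |train| and |test| within one).
Per split: missing features are imputed with train medians, columns are
standardized by train mean and variance (zero-variance train columns are
dropped and logged), the model is fit on the training half only, and AUROC
(Mann-Whitney with ties at 0.5) is computed on the held-out half from the
posterior-mean probabilities. Results aggregate as mean +- SD over the ten
test AUROCs, and per-feature coefficients as the median across folds of
each fold's posterior-median coefficient. Every fold records a SHA-256
hash of its imputed training block so train-only provenance of the scaler
and imputation constants is checkable after the fact.

### Sex interactions and WAIC

Because vocal physiology differs by sex chiefly in fundamental frequency
and harmonicity, the classifier is refit with sex added as a main effect
plus multiplicative sex-by-feature columns for the 7 F0 features and the 2
designated HNR features (9 interaction columns; sex coded female = 0,
male = 1; interaction betas carry the same Laplace prior). Both candidate
models include the sex main effect so the comparison isolates the
interactions. Models are compared per training fold by WAIC,
-2·(lppd - p_waic) with p_waic the summed pointwise posterior
log-likelihood variances. "Substantially better" is quantified as a WAIC
reduction exceeding twice the standard error of the pointwise difference;
ties and sub-threshold differences retain the simpler model, and the
overall verdict is the per-fold majority. This 2-SE rule is deliberately
conservative: in the positive-control simulation (a pure sex x F0
interaction of 2.0 standardized units) every fold shows a positive WAIC
difference but only ~5-7 of 10 clear the threshold, while on
interaction-free cohorts the simpler model is retained in >= 8 of 10 folds.

## Synthetic data

### Audio level

The voice source is a train of band-limited (Hann-windowed sinc) impulses
at fractional sample positions — so cycle timing is accurate to well below
one sample — passed through two cascaded resonators at 700 and 1200 Hz
(bandwidths 80 and 100 Hz), an /a/-like two-formant approximation chosen so
harmonicity and intensity features behave speech-like and the pitch tracker
is stressed by a realistic spectrum. Jitter and shimmer are injected as
i.i.d. Gaussian perturbations (truncated at 3 sigma) of per-cycle period
and amplitude, matching the perturbation-quotient definitions being tested.
Scheduled pauses are silenced; the waveform is scaled to a 0.7 peak to
leave corruption headroom; optional white noise is added at a stated SNR.
A separate corruption operation adds calibrated noise and/or saturates a
stated fraction of samples at full scale, for stressing the QC gates.

The audio generator produces sustained-vowel-like material, not words: it
emulates periodicity, perturbation, noise, level and pause structure, but
no consonants, no lexical content and no longitudinal change. Passing
audio-level tests therefore shows the measurement chain recovers known
signal properties, not that the features capture real dysarthria.

### Feature level

Cohort tables are drawn from a 53-dimensional Gaussian with unit variances
and correlation rho = 0.5 inside each feature category and 0 across
(rate/pause features in real data plausibly measure the same constructs;
the shared-factor block structure emulates that). Group differences are
injected as standardized mean shifts with the convention that positive
means the less-impaired group is higher. Defaults mirror the reference
cohort: 119 patients (47 female) vs 22 controls (12 female); bulbar scores
for patients are a discretized normal matched to median 11, IQR 3, clipped
to 0-12, with ~22% missing (yielding ~93 scored patients); shifts are
homogeneous across patients by default (an optional severity gradient
exists but would deflate the realized control-patient effect size, so it is
off). A canonical effect map (`REFERENCE_EFFECTS`) encodes the salient
clinical pattern — patients slower (speech rate d = +1.5), longer word
units (-1.2), more pausing (-1.0), quieter (+1.0), reduced F0 range
(+1.0), raised shimmer (-1.0), with small jitter/HNR effects. Injected
sex-by-feature interactions are pure: male patients shifted by -delta/2
and female patients by +delta/2, so the implied logistic interaction
coefficient is delta with no main effects added.

The generator is Gaussian; real acoustic features are skewed, heavy-tailed
and nonlinearly inter-dependent. Tests passing on these cohorts validate
the protocol machinery (splitting, standardization hygiene, shrinkage,
aggregation, WAIC decisions), not clinical performance levels: the
reference study's AUROCs (0.85 / 0.78 / 0.70) belong to restricted clinical
data and are not reproduced here.

## Numerical choices and degenerate inputs

* Parabolic refinement is clipped to +-0.5 bin; peaks at array edges are
  used unrefined.
* Frame autocorrelation r is clipped to [1e-6, 1 - 1e-6] before the HNR
  log-ratio; HNR is capped at +-60 dB.
* An all-zero noise profile makes spectral subtraction an exact identity;
  the output is always trimmed/padded to the input length.
* Recordings with no voiced frames yield NaN phonatory features but intact
  timing features; all-silent recordings yield one all-duration pause and
  no speech segments.
* Splits with a class smaller than 2 are rejected; standardization drops
  zero-variance train columns and records them, and a dropped column's
  coefficient is NaN for that fold (median aggregation skips NaN).
* All randomness flows from integer seeds; a pipeline master seed fans out
  to per-stage seeds through SHA-256, so end-to-end runs are bit-exact
  reproducible and feature CSVs re-entering the pipeline (parsed with
  round-trip float precision) give identical downstream results.

## Problem sizes in the shipped checks

The test suite and acceptance script use: 1-2.5 s synthetic vowels;
perturbation-quotient identities on 100 random pulse sequences; AUROC
against pair counting on 200 instances of size <= 20; posterior recovery
at n = 200 with 5 of 53 unit coefficients over 10 seeds; shrinkage at
n = 100 over 10 seeds; the full 119 + 22 cohort with 10 splits for the
separable-cohort, null-label, and WAIC checks. These sizes were chosen so
the complete run finishes in minutes on one CPU while every check retains
clear statistical margins.

## Known limitations

* The exact proprietary 53-feature definitions are unavailable; the
  manifest is a best-effort reconstruction at the category level, and word
  durations are proxied by speech chunks.
* The null-coefficient behaviour of the Laplace(0.5) prior at n = 200 is
  honest but wide: individual null features can carry posterior medians up
  to ~0.5-0.9 by chance association (confirmed against an independent
  sampler), so coefficient magnitudes below ~0.2 should not be read as
  evidence of relevance in cohorts of this size.
* Pause-length class boundaries (0.5 / 1.0 s), the voicing threshold, and
  the syllable-prominence criterion are standard-practice values, not
  protocol-specified ones.
* No mel-frequency cepstral coefficients, formant tracking, resonatory
  features, transcripts, multiclass severity model, or age/education
  covariates.
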