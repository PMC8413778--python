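# Methods

## Scope

`mmnkit` implements a complete analysis chain for auditory mismatch
negativity (MMN) oddball studies comparing two groups: stimulus-sequence
generation, synthetic multichannel epoch simulation, preprocessing,
difference-wave measures, topographic dissimilarity (DISS) randomization
statistics, and 2 x 2 mixed-design group statistics. Because raw
recordings for the study design it targets are not publicly deposited, the
synthetic-data module is a first-class, tested component: it emulates the
statistical structure the analysis assumes so that every stage can be
validated end to end.

## Oddball designs

Two designs are supported. The *simple* (frequency) oddball presents
1131 Hz standards with rare 1269 Hz deviants. The *pattern* oddball
presents rising three-tone triplets (1131, 1198, 1269 Hz) as standards and
the reversed falling triplet as deviants; a unit is a whole triplet, and
epochs are time-locked to triplet-initial tones. Defaults: 200 deviant
units per condition at probability .16 (forcing 1250 units), 180 ms
stimulus-onset asynchrony, 50 ms tone bursts.

Deviant placement is uniformly random subject to at least one standard
unit between consecutive deviant units (configurable `min_standards_
between_deviants`, plus an optional deviant-free head run). Both
constraints are design choices: typical oddball practice keeps deviants
non-adjacent so the regularity stays interpretable, and the source designs
rarely state their exact spacing rules. When `n_deviants / p_deviant` is
not an integer the realized probability is reported in the event-table
metadata; it always lies within 1/total of the requested value.

## Simulation model

Each epoch covers [-100, 400) ms around stimulus onset (500 ms including
the 100 ms baseline). A standard epoch is a fixed P1-N1-P2 obligatory
response — three Gaussian kernels (+1.2 uV at 55 ms, -2.0 uV at 105 ms,
+1.4 uV at 185 ms; FWHM 40/55/80 ms) — times a broad centro-frontal
spatial taper. A deviant epoch adds a negative Gaussian MMN kernel
(default FWHM 60 ms) at the subject's configured latency, weighted by a
cosine-squared fronto-central taper that equals 1 at Fz, peaks around
Fz/FC1/FC2/Cz, and reaches exactly zero at occipital and mastoid sites.
The zero mastoid loading means linked-mastoid re-referencing leaves the Fz
MMN amplitude untouched, so noiseless parameter recovery is exact; no
polarity inversion at the mastoids is modeled (a simplification of
nose-reference physiology). In the pattern condition the obligatory
responses to tones 2-3 are superposed linearly at +180 and +360 ms; they
are identical in standard and deviant first-tone epochs and cancel in the
difference wave.

**Amplitude convention.** Subject profiles carry the Gaussian kernel
*peak* (`mmn_peak_uv`). Published group tables, however, report 50-ms
*window mean* amplitudes. The analytic conversion is
`mean/peak = sigma*sqrt(2*pi)*erf(w/(2*sigma*sqrt(2)))/w` (~0.860 for FWHM
60 ms, w = 50 ms; `mean_window_factor`). The study preset stores cell
means as window-mean amplitudes and converts to kernel peaks, so the
pipeline's measured mean amplitudes recover the configured values. At
512 Hz the measured window spans +/-12 samples (+/-23.4 ms), a ~1%
quantization relative to the continuous +/-25 ms integral.

**Noise.** AR(1) in time (coefficient 0.95 at 512 Hz, burn-in discarded)
with spatially correlated innovations (squared-exponential kernel over 2D
montage distance, length scale 0.35 head radii), scaled to a stationary
per-channel SD. The default SD is 4 uV. This scalar was calibrated once
against the module's stated goal: the preset's between-subject SDs are
reconstructed from published SEMs, which measure the *total* observed
spread, so measurement noise added by the pipeline must remain a minor
contributor. Because AR(1) at 0.95 concentrates power at very low
frequencies, a 50-ms window mean carries nearly the full per-sample noise
SD (variance inflation (1+a)/(1-a) ~ 39), and a minimum-picking latency
estimator latches onto noise troughs once the averaged difference wave's
noise approaches the MMN trough depth. At 4 uV the per-subject measurement
error (latency RMSE ~ 10 ms, window-amplitude RMSE ~ 0.5 uV at the
weakest cell) stays well below the configured between-subject latency SDs
(26-34 ms); at 12 uV it dominated them and distorted recovered cell
means. The scalar is therefore best read as "post-rejection background in
the 1-30 Hz band for a cooperative adult sample", not raw scalp RMS.

**Artifacts.** A configurable fraction of trials (default 5%) receives a
+/-150 uV half-sine excursion (~100 ms) on FP1/FP2 in the post-stimulus
window, guaranteeing a >= 100 uV deflection that the +/-70 uV rejection
stage catches. No ocular or myogenic modeling beyond this.

**Subject draws.** Per-cell normal draws, clipped to the valid MMN latency
range [100, 250] ms (clipping a single draw keeps cell means nearly
unbiased, unlike resampling, which would shift the male simple-condition
mean by ~3 ms because 100 ms sits only 1.6 SD below it); amplitudes are
floored at 0.05 uV. Everything is reproducible from the study seed; per
subject seeds are spawned from it.

What the generator does *not* emulate: continuous raw recordings with
drifts and line noise, ocular components, refractoriness/adaptation of
standards, inter-subject montage variation, or non-Gaussian MMN shapes.
Passing tests therefore demonstrate correctness of the analysis chain
under the stated statistical model, not robustness to every property of
real EEG.

## Preprocessing

Canonical order (enforced and recorded in each epoch set's provenance):
band-pass filter -> linked-mastoid re-reference -> baseline correction ->
amplitude rejection (epoching precedes the chain when starting from a
continuous recording). Choices:

* **Filter**: 4th-order Butterworth band-pass 1-30 Hz, applied
  forward-backward (`sosfiltfilt`) for zero phase. Only the band is
  inherited from the analysis convention; the realization is ours.
* **Epoching**: [-100, 400) ms half-open; sample counts are rounded from
  the window (512 Hz -> 51 pre-stimulus of 256 samples). Events whose
  window leaves the recording are dropped with a logged warning.
* **Rejection**: a trial is rejected iff any scalp channel (mastoids
  excluded) has a sample with |v| strictly above 70 uV after baseline
  correction. "Amplitude variations exceeding +/-70 uV" admits a
  peak-to-peak reading; both are implemented (`rejection_mode`), absolute
  is the default. The boundary is strict (exactly 70.0 uV is retained).
  Rejection runs after re-referencing by default (order configurable in
  code by composing the stages directly).
* **Noiseless recovery runs disable the filter** (`apply_filter=False`): a
  1 Hz high-pass removes several percent of a 60-ms-FWHM Gaussian's
  low-frequency mass, so microvolt-exact recovery through the filter is
  physically impossible; noiseless synthetic epochs are already
  band-limited. Noisy runs keep the filter on.

## MMN measures

The difference wave is deviant minus standard evoked average (retained
trials only; pattern condition uses triplet-initial epochs on both sides).
Peak latency is the global minimum sample at Fz within the closed
100-250 ms window, ties to the earliest sample; a flat window returns the
window start with a `no_unique_peak` flag. Mean amplitude is the mean over
[peak - 25, peak + 25] ms at sample resolution, clamped to the epoch with
a flag when cut, and reported as the magnitude of the negativity (positive
number) with the signed mean retained. Fz-only measurement is the default;
the electrode is a parameter.

## Topographic statistics

GFP is the spatial root-mean-square of the average-referenced map (1/E
normalization), i.e. the spatial SD. DISS average-references both maps,
divides each by its GFP, and returns the root-mean-square difference; the
result lies in [0, 2] with DISS^2 = 2(1 - r). Individual MMN maps are the
per-electrode mean of the difference wave over the subject's own 50-ms
window (peak-sample mode available); the 30 scalp channels enter, mastoids
are excluded. Both the map window and the average-reference-before-GFP
convention are our documented choices — the analysis convention this
follows does not pin them down.

The group test permutes individual maps between groups (sizes preserved),
recomputes DISS between permuted group means, and reports
p = #(DISS_perm >= DISS_obs)/n_perm (ties count toward the null; the
(b+1)/(m+1) estimator is available via `add_one`). Default 10,000
permutations, reproducible by seed.

## Group statistics

The 2 x 2 mixed ANOVA (one two-level within factor, one two-level between
factor) reduces exactly to difference scores (within main effect and
interaction, error = subject x within residual) and subject means (between
main effect, error = subjects within groups); denominator df is N - 2 for
all three effects, and partial eta squared is
SS_effect/(SS_effect + SS_error-of-that-stratum). With unequal group
sizes the within-effect tests use unweighted marginal means (the Type III
convention of mainstream ANOVA software); under imbalance those sums of
squares are not additive, so the SS decomposition is exact on balanced
designs only. Sphericity is moot with two within levels. Degenerate inputs
(all values equal) return zero effects with a `zero_variance` flag rather
than NaNs.

t-tests: classical paired (d = mean difference / SD of differences) and
pooled-variance independent (d = difference of means / pooled SD,
df = n1 + n2 - 2). `t_from_summary` reconstructs group SDs as SEM*sqrt(n)
from printed summaries; its d is reported as a magnitude, and agreement
with published d values is limited by table rounding (~ +/-0.02). The
paired-d convention (SD of differences) is a documented choice; published
paired d values cannot be disambiguated without raw data.

## Numerical and testing choices

* Times in ms, voltages in uV, samples 0-based, epoch windows half-open;
  closed measurement windows at sample resolution with 1e-9 ms tolerance.
* Epoch files are `%.17g` TSV + JSON sidecar: bit-exact round trips.
* Statistical calibration tests fix their seeds and check rejection rates
  against binomial 95% CIs at large simulation counts (10,000 ANOVA null
  draws; 500 DISS datasets x 400 permutations).
* Replicate-level power checks (interaction detected in the majority of
  preset replicates; the small configured pattern-condition gender
  difference, true d ~ 0.26, detected only in a minority) run on the
  generator's subject-parameter draws; the epoch-level pipeline's recovery
  of those draws is validated separately, and one full epoch-level study
  (29 subjects, 512 Hz, 10,000 permutations, ~2 min on one CPU) runs in
  the acceptance script.
* The end-to-end acceptance problem sizes (full 200-deviant sequences,
  29 subjects) match the preset study; nothing is scaled down there.

## Known limitations

* The minimum-sample latency estimator is noise-sensitive by construction
  (no jackknife or fractional-area alternatives are provided).
* The ANOVA is specialized to the 2 x 2 mixed design; it is not a general
  k-way engine.
* DISS is computed at the individual MMN window only; no point-wise
  (per-sample) topographic time courses or microstate segmentation.
* Standard-format EEG import is a thin optional adapter around `mne`;
  channel harmonization with the 32-channel montage is the caller's
  responsibility.
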