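# Methods

`fpas` implements an auditory frequency-tagging (steady-state) oddball
paradigm end to end: stimulus engineering, EEG preprocessing, the
frequency-domain statistics that quantify periodic category-selective
responses, group/individual inference, behavioural signal-detection
scoring, and a synthetic-data generator whose ground truth makes every
stage testable.

## The paradigm and its model

Short sounds are presented back to back at a fixed base rate
`BF = 1/SOA` (4 Hz for 250-ms clips, 7.8125 Hz for 128-ms clips). Every
third sound is drawn from a tagged category (voices), so that category
membership — and nothing else — is periodic at the target rate
`TF = BF/3` (1.333 Hz or 2.604 Hz). A brain response at TF and its
harmonics can only arise if the category is discriminated *and* the
response generalises across its heterogeneous exemplars; responses at BF
and its harmonics index processing shared by all sounds.

In the frequency domain the response model is a sum of sinusoids at
harmonics of BF and TF riding on broadband EEG noise. Because epochs are
re-segmented to an exact integer number of target cycles before the FFT,
every frequency of interest falls exactly on an FFT bin and spectral
leakage at those bins is zero; no window is applied (rectangular), which
is optimal in this zero-leakage regime.

## Stimulus engineering

* **Equalisation and ramps.** All clips are RMS-equalised; 10-ms linear
  on/off ramps prevent clicks. Attentional targets (an orthogonal
  detection task) are the same clips attenuated in RMS by 12.5.
* **Frequency-bin scrambling** builds the spectral control condition:
  the rFFT of a clip is split into 200-Hz bins and, within each bin, the
  component magnitudes and the phases are permuted *independently* (two
  permutations per bin, positive frequencies only; DC and Nyquist are
  left untouched because conjugate symmetry leaves them no freedom). This
  preserves per-bin power exactly — the permutation invariant the tests
  assert at 1e-6 — while destroying harmonic structure more thoroughly
  than a joint permutation would. The original temporal envelope
  (|analytic signal| low-passed at 50 Hz, configurable) is then
  re-imposed by multiplying with the ratio of original to scrambled
  envelope (denominator floored at 1e-3 of its peak), and the RMS is
  re-equalised. The envelope-extraction method and the joint-vs-
  independent shuffling choice are design decisions; both are isolated
  behind `ScrambleConfig`.
* **Sequencing.** Slots whose 0-based index ≡ 2 (mod 3) receive vocal
  clips (uniformly sampled); other slots receive non-vocal clips sampled
  without immediate exemplar repetition, reuse allowed when the pool is
  exhausted. Six attentional targets are placed uniformly among slots
  outside the 2-s fade windows with a minimum spacing of 2 s. Fades are
  linear gain ramps on the summed waveform. All randomisation flows from
  one integer seed; sequences are bit-reproducible.
* **Acoustic descriptors** for matched-set designs: autocorrelation
  pitch (search range 75–600 Hz, the conventional speech range; shortest
  lag within 90% of the strongest peak, parabolic refinement, voicing
  threshold 0.35 on the normalised peak), harmonics-to-noise ratio
  `HNR = 10·log10(r/(1−r))` from the autocorrelation peak r (capped at
  60 dB as r→1), and the amplitude-weighted spectral centre of gravity.
  These are desk-scale re-implementations of the standard measures, not
  bit-compatible with any particular phonetics package.

## EEG preprocessing

Zero-phase (forward–backward) Butterworth band-pass, 0.1–100 Hz,
design order 4 — zero-phase filtering keeps the steady-state phase
structure intact across channels and doubles the effective attenuation
order. Mains components at 50/100/150 Hz are suppressed by an FFT
multi-notch of width 0.5 Hz that replaces in-notch amplitudes with the
mean amplitude of the 1-Hz flanks (phase kept, one-bin linear taper at
the notch edges). Data are downsampled 512→256 Hz by polyphase rational
resampling after the anti-alias band-pass. Epochs of 69 s (2 s before
fade-in to 3 s after fade-out of a 64-s sequence) are cut per
sequence-onset event; noisy channels can be repaired as the mean of
their k = 4 (configurable 3–4) nearest good neighbours by Euclidean
distance on the unit-sphere electrode layout; everything is re-referenced
to the common average. An optional peak-to-peak amplitude threshold
stands in for by-eye epoch rejection and is off by default.

Integer-cycle re-segmentation truncates each epoch to
`floor(available · TF)` target cycles (optionally capped, e.g. at 60 s).
At 256 Hz the 2.604-Hz cycle is not sample-commensurate, so the sample
count is rounded: the integer-cycle property then holds to half a sample
(about 5e-3 cycles), which moves the harmonic off its bin by a few parts
in 10^5 of the bin width — negligible against the half-bin matching
tolerance. The 4/3-Hz case (60.0 s, 80 cycles) is exact.

## Frequency-domain statistics

* **Amplitude spectra** are single-sided and scaled so a bin-centred
  sinusoid of amplitude A yields A at its bin; resolution is 1/duration
  (0.0167 Hz for 60-s epochs).
* **Local-baseline z-scores.** Each bin is compared with surrounding
  bins: z = (amplitude − baseline mean)/baseline SD. Two baseline
  conventions coexist and both are implemented behind `BaselineConfig`:
  for z-scores, 12 candidate bins per side beyond the skipped adjacent
  bin with each side's minimum and maximum dropped (exactly 20 bins
  remain); for baseline subtraction, SNR and the individual test, simply
  10 bins per side beyond the adjacent bin.
* **Calibration caveat (measured, not assumed).** Because the baseline
  mean and SD are estimated from only 20 bins, the z statistic is
  anticonservative relative to its nominal Gaussian reading: under a
  Gaussian null z = √(21/20)·t₁₉, so P(z>2.32) ≈ 0.018 and
  P(z>1.64) ≈ 0.063; the min/max trimming shrinks the SD estimate
  further and pushes P(z>2.32) to ≈ 0.05, and single-spectrum Rayleigh
  bins (before cross-subject averaging) inflate it again. The unit tests
  verify the empirical null against the t-based prediction
  (`null_exceedance`); the nominal 1% reading of z > 2.32 is *not*
  reproduced by this family of statistics and code comments/tests treat
  that as a property of the method, not a bug.
* **Harmonic selection** walks k = 1, 2, … of the fundamental on the
  channel-pooled (mean across channels) grand-averaged spectrum,
  skipping every harmonic that coincides with an integer multiple of the
  base rate (those belong to the base response; the exclusion set is all
  base multiples up to Nyquist), and stops at the first retained
  harmonic with z ≤ 2.32. Frequencies are matched to bins within half a
  bin.
* **Quantification** sums baseline-subtracted amplitudes over the
  selected harmonics per channel (the topography). Note that baseline
  subtraction removes the local noise-floor *mean*, while a
  high-amplitude signal bin measures |A + noise| ≈ A: summed responses
  are therefore systematically conservative by roughly the summed noise
  floor. At realistic noise floors (~0.05–0.1 µV per bin) this
  under-recovery reaches ~5–10% of a 1-µV response; the synthetic
  defaults (below) keep it within the 5% recovery tolerance.
* **SNR spectra** divide each bin by its local baseline mean (≈1 in
  noise). **Individual significance** cuts 23-bin windows around each
  group-level harmonic of the subject's channel-pooled spectrum, sums
  them element-wise, and z-scores the centre against the 20 flanking
  bins (adjacent bins excluded), threshold 1.64.

## Group and behavioural statistics

One-sample and electrode-wise paired t tests are one-tailed
(signal > noise, standard > scrambled) with Bonferroni correction
implemented as p × n_comparisons capped at 1 and thresholded at 0.05;
for one-sample/paired designs Cohen's d = mean/SD = t/√n (an identity
the tests hold to 1e-12). Welch's t accepts printed summary statistics
as well as raw samples (Welch–Satterthwaite df). The Mann–Whitney test
is exact for small tie-free samples and reported both as U and as the
rank-sum W = U + n₁(n₁+1)/2, since software conventions differ. The
outlier rule is a single pass: drop points beyond 3 SD of the
full-sample mean.

d′ = Φ⁻¹(HR) − Φ⁻¹(FAR) under the equal-variance Gaussian model. The
default extreme-rate correction is log-linear (add 0.5/1): its exact
binomial expectation at 40/40 trials is within 0.013 of truth for
sensitivities up to ~2, whereas clipping rates to [1/(2N), 1−1/(2N)]
overshoots by ~0.07 there (clipping remains available). Both corrections
saturate for d′ ≳ 4 at n = 40 — at most one error is expressible — so
recovery there is checked against the estimator's exact expectation
rather than the true value.

## Synthetic data: what it emulates and what it does not

`SSEPGroundTruth` builds 128-channel epochs as phase-locked sinusoids at
the base harmonics (default amplitudes 1.0, 0.5 µV, broad
centro-occipital topography) and the target harmonics (default 0.4, 0.3,
0.2, 0.1 µV at 1.333/2.667/5.333/6.667 Hz, concentrated on the
right-superior-temporal electrodes TP8h, CP6, C6, T8 so ROI code paths
run under their real names), plus per-channel frequency-shaped Gaussian
noise: amplitude floor `noise_scale · f^−0.7` (clamped below 0.5 Hz)
with flat extra noise `alpha_amp` in 8–13 Hz. Noise is independent
across channels. Cohorts draw per-subject multiplicative amplitude
jitter (SD 0.2) and fresh response phases, and record every subject's
true scale in a ledger for recovery scoring.

Defaults are chosen so that ground-truth recovery through the full chain
is determined by the method, not by simulation noise: `noise_scale =
0.025` µV keeps the conservative amplitude bias described above near 2%
of the 1-µV summed target response and gives the weakest harmonic a
comfortable pooled-detection margin. This is cleaner than typical
recordings — single-sequence ROI SNR here is ~20 versus the ~7
achievable experimentally — so passing recovery tests certifies the
correctness of the chain, not its statistical power at realistic noise;
the √N SNR-growth law, which is scale-free, is checked separately. The
generator also does not emulate: spatially correlated noise (available
conceptually but off), non-stationarity or artifacts, volume-conducted
topography from dipolar sources, or between-harmonic phase structure.

Because subjects' epochs are averaged before the FFT and the noise is
complex-Gaussian in the frequency domain, the cohort workflows draw each
subject's 4-epoch average directly at noise/√4 — exactly equivalent in
distribution and 4× cheaper. Audio corpora synthesise vocal-like clips
(harmonic complexes, f0 ~ N(220, 7²) Hz, formant-shaped envelopes at
500/1500/2500 Hz, slight jitter, noise set for HNR ~ N(21, 2.5²) dB)
against either inharmonic tone-cluster/noise non-vocal sounds or, in the
matched variant, instrument-like harmonic tones drawn from the *same* f0
and HNR distributions, so pitch/harmonicity comparisons are null by
construction and only timbre differs.

## Numerical choices and degenerate inputs

Zero-SD baselines yield ±inf z (flagged, not raised); silence is
rejected where a ratio is undefined (RMS equalisation, spectral
centroid); edge bins without enough baseline neighbours are NaN in
subtracted/SNR spectra and errors when tested directly; out-of-bounds
epochs are skipped with a log entry; event onsets are stored in seconds
so resampling cannot shift them. Monte-Carlo study sizes (100 cohort
repetitions, 5000 observers, ≥10⁴ null bins, 20 SNR repetitions) were
chosen to put binomial/standard errors well inside the asserted
tolerances while keeping a full run in minutes on one core.

## Known limitations

* The local-baseline z statistic does not achieve its nominal Gaussian
  calibration (see above); harmonic selection inherits a ~5% per-walk
  chance of extending one harmonic past the injected set.
* Summed baseline-subtracted amplitudes are conservative by the summed
  noise floor; between-condition *contrasts* are unaffected (the bias
  cancels in paired differences).
* Pitch/HNR estimators are deliberately simple; octave errors are
  guarded but not impossible for strongly inharmonic inputs.
* EDF/BDF reading is supported; writing uses the package's HDF5
  container only.
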