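# Methods

This note records the model, the estimator choices, and the design decisions
behind `emgsynergy`, in enough detail that a maintainer can judge what the
package's tests do and do not establish.

## Signal model and generator

Real recordings of the protocol this package targets (5-channel surface EMG —
mDEL, FCR, FDS, ECR, EDC — at 1,000 Hz; hand open / grasp / relax held 5 s
per trial, 10–12 repetitions, under table / 25% / 50% shoulder-abduction
loading) are not publicly available, so every claim is tested against a
generative model that reproduces the structure the method exploits:

* **Carrier.** Each channel is zero-mean Gaussian noise band-limited to
  5–400 Hz (unit variance), multiplied by an amplitude envelope.  Surface EMG
  carries power down to the conventional 5-Hz conditioning edge; a carrier
  floor above that edge would leave a spectral hole in which coherence is
  numerically degenerate.
* **Task envelopes.** Trapezoidal (250-ms rise/fall).  Resting amplitude is
  0.25 carrier units per channel; a fully recruited muscle adds its voluntary
  gain — 1.0 for the shoulder abductor, 0.4 for the distal muscles.  The
  deliberately low distal gain encodes weak paretic voluntary activation;
  grasp activates FCR/FDS, open activates ECR/EDC, and mDEL is active in
  every trial in proportion to the loading.  Voluntary effort carries a
  lognormal per-trial jitter (σ = 0.3).
* **Synergy drive.** A single band-limited (default 8–13 Hz, jittered per
  subject) unit-variance process per trial is added to mDEL, FCR and FDS with
  gain `severity × gain(loading) × jitter`, where gain(loading) is 0 / 1.0 /
  2.0 for table / sabd25 / sabd50 and the lognormal jitter (σ = 0.4) models
  fluctuating synergy expression.  The drive is present in *all* tasks,
  including relax — that is the phenomenon.  A small broadband involuntary
  co-contraction (0.1 × the alpha gain) of the same flexors rides along:
  flexion synergy activates the muscle, not only the coherent drive.
* **Voluntary beta drive.** A 15–30 Hz process shared among the distal
  agonists of the current task (gain 0.3), standing in for corticospinal
  common drive.  mDEL does not share it, so abductor–distal coherence
  concentrates in the alpha band, as intended.
* **Severity.** A scalar in [0, 1] multiplying the synergy gain; severity 0
  is a control subject.  `make_cohort` draws severities uniformly in a range
  and jitters each subject's synergy band center (9–12 Hz) and width
  (4–6 Hz) so no two subjects share a band.
* **Determinism.** Every trial's randomness comes from a substream keyed by
  (seed, subject, task, loading, repetition); any trial can be regenerated in
  isolation.

With these defaults, unfiltered classification at SABD50 lands at roughly
80–98% across a severity 0.5–1.0 cohort and the filter's per-subject effect
ranges from about −1 to +4 percentage points with a positive mean — the same
qualitative pattern as the motivating experiments (mostly small improvements,
occasional small reductions, controls excluded).  What the generator does
*not* model: motor-unit physiology, rectification-demodulated firing-rate
coherence, electrode artifacts, fatigue drift, or the kinematics of the
2-s arm-lift phase.  Passing tests therefore establish that the pipeline
implements the method correctly and behaves as claimed *under this model*,
not that the clinical effect size transfers to real patients.

## Wavelet coherence

* Morlet wavelet, ω₀ = 6 (Torrence–Compo normalisation, FFT implementation,
  zero-padded to the next fast length ≥ 2n).
* Frequency grid: 60 logarithmically spaced points over 5–60 Hz.  The floor
  sits at the 5-Hz preprocessing high-pass — below it the data contain only
  filter noise; the ceiling leaves margin above the beta band.
* Smoothing: Gaussian in time with sd = scale/√2 (circular FFT convolution;
  wrap-around is confined to the cone-excluded edges and the identical
  positive kernel in numerator and denominator keeps the estimate in [0, 1]);
  boxcar over 0.6 octave across scales; the s⁻¹ weighting of the
  cross/auto spectra.  Unsmoothed wavelet coherence is identically 1, so the
  smoother is part of the estimator.
* Cone of influence: e-folding time √2 · scale; out-of-cone points are
  excluded from aggregation, thresholding and calibration.
* Working rate: inputs are decimated (scipy's zero-phase Chebyshev decimator)
  to ≤ 200 Hz before transforming; the analysis band ends at 60 Hz, so this
  only removes unused bandwidth.  Surrogates pass through the identical path.
* Conditioning: demeaning only.  Full-wave rectification is available
  (`CoherenceConfig.rectify`) but off by default: in the additive-drive model
  the synergy component is coherent in the raw signal, and rectification
  relocates narrow-band energy to DC and twice the band, destroying band
  identification.  For real data where the drive lives in motor-unit firing
  rates rather than an additive component, rectification may be the right
  choice; the flag exists for that purpose.

## Monte-Carlo significance

The per-frequency threshold is the (1 − α) quantile (α = 0.05) of coherence
pooled over in-cone time across `n_surrogates` (default 300, minimum 100)
independent surrogate pairs, computed per muscle pair and per task signal.

* **Null model.** Default is *spectrally matched Gaussian surrogates*: each
  channel's Welch PSD (Hann, ≤ 1024-sample segments at the working rate) is
  resampled onto the surrogate grid and realised with independent Gaussian
  spectral amplitudes and phases.  A classic AR(1) red-noise null and a white
  null remain available (`surrogate_model`).  The spectral null is the
  default because band-limited EMG violates AR(1) badly: below the carrier
  band the in-band spectral slope is steep, the wavelet-coefficient process
  becomes locally narrowband, and an AR(1)-calibrated threshold is far too
  low — in testing, every severity-0 control acquired false significant
  bands under the AR(1) null, while the spectral null removes them and still
  reproduces the nominal 5% exceedance when the inputs really are AR(1).
  The known cost: when the data contain a strong genuine shared oscillation,
  its spectral peak enters the null and the threshold rises locally — the
  procedure is conservative near true coupling, which testing shows it can
  afford (true-band coherence approaches 1).
* **Surrogate length** is fixed at 10 s (configurable) rather than the data
  length: the pointwise null distribution of smoothed coherence depends on
  the smoothing footprint, not the record length, and a fixed length bounds
  the Monte-Carlo cost on long concatenations.
* **Steady phase.** Before coherence, 0.5 s is trimmed from each end of every
  repetition (`SynergyFilterConfig.steady_margin_s`).  Task onset/offset
  produces synchronized amplitude transients in every muscle pair; they are
  not oscillatory coupling, but they bias low-frequency coherence upward.
  The holding phase is where intermuscular coherence is meaningfully defined.

Global (time-aggregated) coherence averages the map over in-cone time per
frequency; a frequency is *significant* when it exceeds its threshold for at
least 25% of in-cone time (`occupancy`).  Momentary crossings occur at the
nominal false-alarm rate by construction, so a sustained-coupling rule is
needed to turn a time-resolved map into a per-frequency verdict; 0.25 is low
enough to tolerate per-trial gaps in the drive and high enough that pooled
5% noise never reaches it in practice.

## Filter design

Significant bands are extracted as maximal runs of significant grid
frequencies (single-point runs are "peak-only"), merged across the three hand
tasks by interval union, and vetted by the exclusion rule: a subject with no
band, or only peak-only / sub-minimum-width bands, receives no filter and is
flagged excluded from before/after statistics.  Eligible bands become one
4th-order Butterworth band-stop per band (second-order sections, stability
checked on the poles), cascaded per channel, applied forward–backward (which
squares the magnitude response).  Bands narrower than 2 Hz are padded
symmetrically before design — very narrow IIR notches are numerically
fragile.  Only the four distal channels are ever filtered, each with its own
mDEL-pair bands; the abductor itself is left untouched.  Filtering is applied
per repetition segment: the splices of a concatenated signal are artificial
discontinuities that otherwise ring through a narrow zero-phase band-stop
and contaminate nearby analysis windows.

## Features and classifier

* Windows: 250 ms advancing by 125 ms from sample 0; trailing windows
  truncate at the signal end, so N samples yield ceil(N/step) windows (the
  convention that makes 12 × 5 s × 3 tasks come out at exactly 1,440 windows).
  A window belongs to the repetition containing its first sample.
* Features per channel per window: zero crossings and slope sign changes with
  an amplitude deadband ε (default 1% of per-channel RMS; the deadband
  suppresses noise-floor counts), mean absolute value, waveform length.
* Classifier: Gaussian equal-covariance Bayes rule (LDA) with the pooled
  within-class covariance shrunk toward a scaled identity,
  (1−λ)S + λ·tr(S)/p·I.  λ is selected from {0, 10⁻⁴, 10⁻³, 10⁻², 10⁻¹} by
  stratified k-fold cross-validation at repetition granularity (k = 10, or
  the repetition count if smaller); ties go to the smallest λ.  Posterior
  ties break toward the earlier class in canonical order (relax, open,
  grasp).
* Splits: 75/25 stratified by task, assigning whole repetitions to one side —
  50%-overlapping windows are strongly dependent, and window-level splits
  would leak.
* Accuracy: per-task percent correct; overall accuracy is the unweighted mean
  of the three per-task accuracies; the filter's effect is the paired
  difference (with − without) in percentage points on a shared split.

## Pipeline

`run_subject` executes both arms for one subject and loading with a single
shared repetition split and seed, so the comparison isolates the filter; when
the exclusion rule fires the arms coincide and the subject's improvement is
undefined.  `run_cohort` repeats this over a cohort and reports per-subject
rows plus mean ± SE of improvement over non-excluded subjects per loading.
No inferential statistics (ANOVA etc.) are computed.

## Problem sizes used in the checks

The packaged checks run at desk scale: significance calibration pools 50
AR(1) pairs of 10 s at the full 300-surrogate default; band recovery uses
20 runs of 60-s pairs; the cohort comparison uses 12 stroke profiles
(severity 0.5–1.0) and 8 controls with 6 repetitions of 3-s trials, 100
surrogates, and improvements averaged over two independent splits per
subject.  The windowing arithmetic check uses the full 12 × 5 s protocol.

## Known limitations

* The additive narrow-band synergy component is a stand-in; the true spectral
  shape of synergy-induced EMG is unknown, and the generator is labelled
  accordingly.
* The spectral null is conservative exactly where coupling is strong; bands
  recovered from weak true coupling (near-threshold SNR) will be clipped
  before bands from strong coupling are.
* Detected stop bands are wider than the injected drive band (wavelet
  bandwidth plus scale smoothing smear a 8–13 Hz drive to roughly 5–18 Hz);
  the filter consequently removes some voluntary content near the band edges.
* Everything is offline; no causal/real-time variant is provided.
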