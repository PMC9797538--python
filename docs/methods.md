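# Methods

`postphase` quantifies postural-control adaptation in a six-phase
VR/moving-platform protocol from three simultaneously recorded biosignals,
and asks how well the experimental phase can be decoded from per-phase
feature batteries. This note documents the models, the parameter choices,
and what the synthetic cohort does and does not establish.

## The protocol and its segmentation

The protocol is a fixed timeline: a 2-min quiet-stance baseline with a
static scene (**BL**), a 40-s visual onset with the sea scene but a still
platform (**PRE**), three 40-s platform-motion phases at 25/50/75 % of
maximum amplitude (**P25/P50/P75**), and a 40-s **POST** phase in which
motion stops abruptly while the scene continues. Platform intensity is
therefore the vector (0, 0, 0.25, 0.50, 0.75, 0) over the six phases.

Per-modality analysis windows:

* **EEG** — the first and last 5 s of every phase are discarded (transition
  artifacts); for BL only the last 60 s are retained before trimming, so
  50 s of BL and 30 s of each 40-s phase are analyzed. Trimming is applied
  to the retained 60 s, not the full 2 min; the order of operations is a
  package decision.
* **EMG** — the central 20 s of each phase (for BL: the central 20 s of its
  last 60 s). Central placement is the symmetric reading of
  "remove the transitions"; the exact rule is not fixed by the protocol.
* **CoP** — the platform recording starts only after BL, so CoP has five
  full 40-s windows (PRE…POST) and no baseline segment.

Sample indexing is half-open and 0-based: a window (t0, t1) at rate fs is
samples [round(t0·fs), round(t1·fs)), which makes the sample-count formula
exact and windows non-overlapping.

## Feature batteries

**EEG (25 features).** Signals are resampled to 1,024 Hz if needed,
band-passed 1–45 Hz (4th-order Butterworth, zero-phase) and notch-filtered
at 50 Hz. Welch PSD uses 2-s Hann windows with 50 % overlap — long enough
for two cycles at the 1-Hz band edge; mean (not median) segment averaging.
Relative power in delta (1–4), theta (4–8), alpha (8–13), beta (13–30) and
low-gamma (30–45 Hz) is normalized by total 1–45 Hz power, so each
channel's five shares sum to 1 and are invariant to channel gain. Shares
are averaged over five cortical lobes (frontal, parietal, occipital, two
temporal) using an editable 64-channel 10-10 assignment table
(`data/lobe_map_1010.tsv`); central and fronto-central rows are assigned
to the nearest lobe (parietal and frontal respectively) since the scheme
has no central lobe. Automated artifact pipelines (ICA-based removal, bad
electrode interpolation) are out of scope: preprocessing is deterministic
filtering only.

**EMG (43 features × 6 channels = 258).** Channels are TA/GL/SOL × L/R at
1,600 Hz, conditioned by a zero-phase 4th-order Butterworth band-pass of
15–500 Hz. The battery is a canonical surface-EMG set: 29 time-domain
operators (MAV, IEMG, SSI, RMS, VAR, SD, WL, AAC, MAD, DASDV, LDASDV, ZC,
SSC, WAMP, MYOP, LOG, MFL, MSR, PEAK, CREST, SKEW, KURT, TKEO mean, LTKEO,
Hjorth mobility/complexity, 3rd–5th temporal moments) and 14 Welch-PSD
descriptors (MNF, MDF, peak frequency, total/mean power, spectral moments
1–3, low/high frequency ratio, centroid variance, spectral entropy, 95 %
spectral edge, low/high band-power fractions). Choices pinned down here
because they are not universal:

* TKEO is Ψ[x](n) = x(n)² − x(n−1)·x(n+1); LTKEO = ln(mean |Ψ| + ε) with
  ε = 1e−12. The rectified mean keeps the logarithm defined; natural log.
* DASDV uses the N−1 normalization; LDASDV = ln(DASDV + ε).
* MFL = log10 of the Euclidean norm of the first differences, which obeys
  MFL = ½·log10(N−1) + log10(DASDV) exactly.
* ZC/SSC use zero thresholds (no hysteresis); WAMP/MYOP use a 0.02 mV
  (20 µV) threshold, the conventional level for surface EMG.
* Every logarithm is ε-guarded so constant segments degrade to finite
  values instead of aborting batch extraction; a non-finite feature raises
  an error naming the operator and channel.

**CoP (35 features).** Raw platform output is a pair of sensor percentages
in [−1, 1]; displacement in cm is `dimension × 0.5 × percentage` per axis
(ML along the platform's X, AP along Y; default geometry 50 × 50 cm is
used only where no explicit geometry is supplied). The stabilogram is
smoothed with a Savitzky–Golay filter, window 7; the polynomial order is
not standardized anywhere, order 3 is the common default compatible with
that window. The battery follows the standard posturography measure set:
mean and RMS distances (per axis and resultant — RDIST equals the
population SD, N denominator, distinguishing it from the sample SD
features), sway-path lengths and mean velocities, ranges, 95 %
confidence-circle and confidence-ellipse areas (the ellipse via the
χ²(2, 0.95) = 5.99 scaling of the 2-D covariance determinant), sway area,
rotational mean frequencies, three fractal dimensions, per-axis median /
95 %-edge / centroid frequencies, an ML/AP dispersion ratio, and the
step-direction Shannon entropy. Direction entropy — named but nowhere
defined in the posturography feature lists we mirror — is implemented as
the entropy (bits) of the 36-bin histogram of step angles
atan2(ΔAP, ΔML), zero-length steps discarded: 0 for straight-line motion,
log2 36 ≈ 5.17 for isotropic sway. All features are computed on
mean-centered axes, making the whole battery invariant under constant
translation of the trajectory.

## Feature ranking

Features are ranked by one-way fixed-effects ANOVA F across the phase
classes, with effect size η² = SS_between/SS_total and a 95 %
bias-corrected bootstrap CI (2,000 resamples, seeded). "η² at a 95 %
confidence level" is read as a CI on η²; the bootstrap is preferred over
noncentral-F inversion for robustness to the non-normal feature
distributions. Ties are broken lexicographically by feature name;
constant features receive F = 0 with a warning. No multiple-testing
correction is applied — the F values order features, they are not used
for inference. Samples (subject × phase rows) are treated as independent
even though phases repeat within subject; this replicates the original
analysis design and is a known caveat for the p-values, not the ranking.

## Classification

Phase sets can be merged: six phases; five (no BL, the CoP-compatible
set); four or three with P25/P50/P75 averaged into one movement class; and
binary BL-vs-rest. Merging averages a subject's per-phase feature
vectors, which is unbiased here because the design is balanced (one vector
per subject per phase). Requesting CoP together with a BL-containing
configuration is an error by construction.

The model family is linear discriminant analysis, linear- and
Gaussian-kernel SVMs (kernel scale from the standard median heuristic in
scikit-learn's `gamma="scale"`), and a random-subspace ensemble of 30
linear discriminants on ⌈p/2⌉-dimensional feature subsets — conventional
defaults, as the ensemble's hyperparameters are not standardized.
Features are z-scored inside each training fold. Validation accuracy and
macro one-vs-rest AUC come from stratified 10-fold CV on the training
split; the best-by-validation model is refit on all training data and
evaluated once on a held-out test split (default 20 %; the source
protocol states both 80/20 and 70/30 — 0.2 is the default and it is
configurable). Splitting is grouped by subject by default so no subject
spans the train/test boundary; a flag restores row-level splitting.
Reported per configuration: validation/test accuracy, validation/test
macro AUC, the K×K confusion matrix with per-class TPR/FNR, the per-model
comparison, and the top-ranked features.

## The synthetic cohort

No public recordings exist for this protocol, so the package ships a
generator whose *phase-dependent statistical structure* mirrors the study:

* **EEG**: 1/f background (10 µV RMS) plus band-limited alpha and
  low-gamma components; from PRE onward, occipital low-gamma and
  frontal/parietal alpha amplitudes scale by (1 + `visual_onset_eeg`).
  EEG carries only this visual-onset step, so EEG separates BL from the
  rest but not the motion phases — the qualitative outcome of the study.
  EEG is synthesized directly at 1,024 Hz (the post-resampling rate the
  pipeline sees).
* **EMG**: 15–500 Hz noise (10 µV RMS baseline) amplitude-modulated by a
  homogeneous Poisson burst process (0.3-s Hann envelopes). Burst rate
  (0.2 + 2·drive per second) and amplitude (3× baseline × (1 + drive))
  scale with drive = `platform_gain` × intensity, plus `post_ap_gain` in
  POST — the perturbed POST phase elicits corrective muscle activity,
  which is what lets burst-energy features separate POST from BL/PRE.
* **CoP**: a fixed quiet-stance AR(1) (discrete Ornstein–Uhlenbeck, pole
  0.98 at 90 Hz, stationary SD 3 % of the sensor range) plus an additive
  platform/scene-driven wave-band component (0.5–2.5 Hz nominal). The
  wave *amplitude* scales with drive on ML (0.3 × drive on AP, plus
  `post_ap_gain` on AP in POST); its frequency band is scaled by a
  per-subject log-normal tempo factor (σ = 0.3), and the AP response
  amplitude by a per-subject log-normal style factor (σ = 0.6). This
  construction is deliberate: the phase contrast lands in the ML sway
  *dispersion* statistics (RDIST_ML, SD_ML), while sway-velocity,
  sway-frequency and AP measures inherit the between-subject spread —
  reproducing the study's finding that ML dispersion features dominate
  the CoP ranking and that AP responses are the most individual.

Between-subject heterogeneity multiplies the three response gains by
independent log-normal factors (σ = 0.2). All subject-level variability
enters *through the gains*, so the null profile (all gains zero) yields
signals that are exchangeable across phases and homogeneous across
subjects — under it, phase-ANOVA p-values are uniform and classification
accuracy is at chance, which the acceptance suite verifies.

Default gains (`EffectProfile()`: visual 1.0, platform 3.0, post-AP 2.0)
are the package's standard study conditions, chosen once so the planted
EMG/CoP contrasts are unambiguously large (the leading features reach
η² ≈ 0.8–0.95, computed by the acceptance script) while the EEG effect is
a visual-onset step only. Everything is deterministic
given (seed, parameters); per-subject seeds derive from the master seed
via `SeedSequence`. EEG/EMG noise is synthesized in float32 (band-limited
noise directly in the frequency domain) purely for speed; all analysis is
float64.

**What the synthetic cohort does not show.** It contains no real
electrophysiology: no artifacts, no volume conduction or electrode
geometry, no muscle fatigue, no non-stationary adaptation within a phase,
and its sway is Gaussian. Passing tests demonstrate that the pipeline
recovers structure that is planted and finds nothing when nothing is
planted — they do not certify the original study's real-data accuracies,
which require the (unavailable) cohort.

## Problem sizes and numerical choices

The acceptance suite and `scripts/acceptance.py` use 60-subject cohorts
(10 master seeds for the null calibration, one for effect recovery) —
large enough for stable splits (12 held-out subjects) while keeping a full
run in minutes. Degenerate inputs are contracts, not crashes: zero
channels and all-zero steps raise informative errors; constant features
rank last with F = 0; zero within-class variance with unequal means
reports F = +∞ with p = 0. Filters are zero-phase throughout so features
never depend on group delay.

## Known limitations

* The exact 43-EMG and 35-CoP feature lists of the original study are in
  unavailable supplementary material; the batteries here are canonical
  sets pinned to the same counts and containing every named member.
* The electrode-to-lobe assignment is a reasonable 10-10 mapping, not the
  study's (unpublished) one; it is an editable data file.
* ANOVA ignores within-subject correlation across phases (by design,
  replicating the original analysis).
* The real platform geometry is unpublished; displacement tests always
  pass geometry explicitly so the 50 cm default never silently matters.
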