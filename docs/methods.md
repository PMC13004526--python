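# Methods

`thetagaze` implements an analysis pipeline linking saccadic eye movements to
medial-temporal-lobe (MTL) theta activity during ambulatory navigation, in
which participants alternate between memory-cued (MC) navigation to a
remembered hidden target and visually-cued (VC) navigation to a visible wall
sign. Because the corresponding patient recordings are not bundled, every
stage is developed and validated against a synthetic-session generator with
known ground truth. This note records the models, parameter choices, and
numerical decisions.

## Data model

All streams share one session clock (seconds, t = 0 at session start) and
keep their native timestamps — nothing is resampled implicitly. Gaze lives
in a normalized 192 x 192 reference frame at ~200 Hz; body position in
meters (room default 5.9 x 5.2 m) at 120 Hz; bipolar iEEG at 250 Hz, stored
in non-overlapping recording intervals of up to ~3.5-4 min, which are the
unit for all per-interval statistics (z-scoring, IED baselines). Invalid
gaze samples (blinks, dropouts) are carried with `valid=False` and skipped
downstream, never interpolated. The interchange format is a directory of
CSV files plus a YAML manifest; there is no public standard for this
multi-stream bundle, and CSV keeps the test surface language-agnostic. EDF
ingestion is out of scope for this release.

## Synthetic sessions

The generator emulates the statistical structure each stage assumes, not
biomechanics:

* **Gaze.** Alternating fixations (anchor + isotropic Gaussian noise,
  default SD 0.3 px — on the order of the reported eye-tracker precision in
  frame units) and saccades with a minimum-jerk displacement profile
  (single-peaked, bell-shaped velocity). Durations are gamma distributed —
  the source distributions are unpublished; gamma keeps durations positive
  and right-skewed — with means anchored to the MC condition values
  (saccade 89 ms, fixation 342 ms; shapes 6 and 4). Amplitudes are gamma
  (mean 20 px, shape 2.5, floor 5 px) with reflection at the frame border.
* **iEEG.** Each channel is 1/f^alpha Gaussian noise (spectrally shaped
  white noise, alpha = 1) plus one theta oscillator at 6.5 Hz of baseline
  amplitude 1 background-SD. Power locking multiplies the theta amplitude
  by `power_lock_gain` (default 2.5, a moderate effect chosen so a
  five-participant study has high power) in a 0-200 ms window after each
  saccade onset, optionally restricted to one condition (default MC),
  mirroring the analysis epoch. Phase locking resets the oscillator phase
  to a fixed angle at saccade onset. Interictal discharges (IEDs) are
  biphasic derivative-of-Gaussian transients (~100 ms, 8-12 background SD)
  at 0.05 events/s, which together with the exclusion smearing removes
  ~1-2% of samples — the range reported for the patient recordings.
* **Trials and path.** Alternating VC/MC trials (20 s + 1 s standstill
  gap); MC walks insert a lateral detour waypoint so the walked distance
  equals `straight x (1 + detour/100)` exactly (detour truth gamma, mean
  30%); the second half of each trial is walked 1.5x faster, reproducing
  the planning -> execution speed-up.

One master seed expands to per-stream child seeds (`SeedSequence`), so every
stream is independently reproducible. What the generator does **not**
emulate: saccadic suppression, eye-in-head geometry, non-stationary 1/f
background, spatially tuned (place/grid) activity, realistic IED morphology
variety. Passing tests therefore demonstrate correctness of the pipeline's
bookkeeping and inference under the assumed generative structure, not
real-data effect sizes.

A hard phase reset is a discontinuity: it transiently broadens the spectrum
and can slightly *reduce* measured narrow-band theta power around saccade
onset. Phase-locked-only sessions consequently show a small negative power
contrast; the one-sided tests (directional: saccade > fixation) read this
as null, which is the behavior the dissociation check requires.

## Eye-movement classification

Cluster-Fix-style: k-means over per-sample speed, acceleration magnitude,
angular change, and point-to-point displacement (the displacement feature is
point-to-point, not window-cumulative). Positions are smoothed with a short
(~20 ms, odd-length) centered moving average before differentiation — raw
differentiation at 200 Hz is noise-dominated; the window length is
configurable and forced odd to avoid a half-sample phase shift. Magnitude
features are log1p-compressed before standardization: their raw
distributions are so heavy-tailed that Euclidean k-means otherwise crushes
small saccades into the fixation cluster. k is selected from {2..5} by
silhouette score (subsampled, seeded). The cluster with the lowest combined
standardized speed + acceleration seeds the fixation class; clusters whose
centroid lies within 3 SD of that cluster's mean on the same axis are
absorbed into fixation; the rest are saccades.

Two refinements sharpen event boundaries: (1) each detected saccade run is
extended outward while the neighboring sample's speed or acceleration
exceeds a robust fixation-level threshold (median + 3 MAD-scaled SD of
fixation-labeled samples, floored at 10% of the median saccade-core value so
noise-free fixations do not absorb smoothing leakage; the trailing edge uses
speed only, because deceleration leaks one sample past the motion); (2)
events shorter than 2 samples are merged into the flanking state. On
default-noise synthetic sessions the classifier reaches ~96% sample accuracy
with a median onset error of 1 sample; at zero noise ~98.5% — one sample
per event boundary is kinematically ambiguous by construction (the
minimum-jerk onset sample has not yet moved; the first post-offset sample
carries the deceleration transient).

Scanpath entropy uses a 30 x 30 occupancy grid over the gaze frame and
Shannon entropy in 1-s sliding windows, reported in bits (base 2; only
median splits are consumed downstream, which are base-invariant). Saccade
frequency uses 1-s windows at 4 ms steps. Median splits assign ties to the
low group (deterministic, balance within 1).

## IED exclusion

Double-threshold detector per channel and recording interval: a sample is
flagged when the Hilbert-analytic envelope of the raw signal, or of the
15-80 Hz band-passed signal, exceeds 6 SD above baseline. "Baseline" is
read as robust per-interval statistics (median, MAD-scaled SD) so the
discharges themselves do not inflate the threshold. The binary detection
vector is smeared with a Gaussian kernel of total length 0.05 s
(sigma = window/5, unit-sum, truncated) and samples whose smoothed value
exceeds 0.01 join the exclusion mask; the smeared run always contains the
detected run. The total excluded width around an isolated discharge then
depends on the detected-event duration and the kernel parameterization, so
the ~250 ms figure quoted for real data is treated as descriptive, not as a
reproducible constant. Peri-saccade power epochs touching any masked sample
are dropped entirely (the conservative reading; per-sample invalidation is
available as an option).

## Spectral analysis

Complex Morlet wavelets with sigma_t = cycles/(2 pi f), unit-energy
normalized, 6 cycles for main analyses and 3 cycles for the
temporal-resolution control, on a grid of 2-30 Hz in 0.25 Hz steps plus
31-80 Hz in 1 Hz steps (163 frequencies). Power is computed per recording
interval; samples within one wavelet half-support (3.5 sigma_t) of an
interval edge are flagged unreliable and excluded from statistics. Power is
z-scored per frequency, per interval, per channel over unmasked, non-edge
samples; band power (theta 5-8 Hz: 13 bins; low-frequency 3-15 Hz: 49 bins;
gamma 45-80 Hz) is the mean of z-power across band bins, inclusive.

Oscillation bouts (BOSC-style): the background is a robust Theil-Sen fit of
log10 mean power against log10 frequency over the full grid (no peak
exclusion, matching the standard procedure); the power threshold at each
frequency is the 95th percentile of a chi-square(2) distribution scaled so
its mean equals the fitted background power (the standard assumption for
wavelet power of Gaussian noise); a bout must exceed the threshold
continuously for at least 2 cycles. Pepisode(f) is the fraction of unmasked
samples inside bouts; it is invariant to overall signal rescaling because
the fitted background rescales accordingly. Bout-prevalence summaries
default to the 4-25 Hz range.

## Peri-saccade alignment and phase

Power epochs cover -100..+200 ms around saccade onset in 4 ms steps (76
points; one iEEG sample at 250 Hz). Pre-onset samples overlapping an
earlier saccade and post-onset samples beyond the epoch's own saccade offset
are invalidated, so the number of contributing events is non-increasing
after onset. Epoch normalization references the pooled mean/SD of the band
series across all fixation and saccade periods in both task conditions.

Theta phase comes from a zero-phase FIR band-pass (5-8 Hz, 501 taps at 250
Hz, filtfilt) followed by the analytic signal, per recording interval;
wavelet phase at a single frequency is an equivalent alternative and both
satisfy the same estimator oracles. Pairwise phase consistency (PPC) across
events is computed by the closed form (N^2 R^2 - N)/(N (N-1)), which equals
the mean cosine of all pairwise phase differences (kept as an explicit
brute-force oracle in the test suite); it is unbiased, with range
[-1/(N-1), 1]. The PPC time course covers -800..+208 ms; window means are
reported for the saccade window (-50..+200 ms) and the equal-duration
baseline (-800..-550 ms). Phase epochs are invalidated only by IED-masked
samples: the baseline window predates onset by over half a second, so the
power-epoch fixation-overlap exclusion cannot apply to it. PPC is computed
per channel and aggregated across channels at the statistics stage.

## Statistics

Unequal sample counts between compared states are balanced by subsampling
the larger group, without replacement, to the smaller group's size,
recomputing the statistic, and averaging over 500 iterations (seeded).

Channel-level group inference uses one-sided permutation tests with
exchangeability restricted within participants. The observed statistic is
the across-channel one-sample t of the per-channel effect values (the
aggregation is an interpretation; the source text reports t without defining
it). The sign-flip null flips all of a participant's channels together —
the conservative scheme when channels within a participant are dependent;
per-channel flipping is available behind a flag. Paired condition
comparisons exchange labels within participant, which reduces to the same
block-synchronized sign-flip on the per-channel differences. When the
number of blocks is small (<= 20) the null is enumerated exhaustively and
the attainable-p floor is reported: with 5 participants there are 32 sign
patterns and the smallest attainable p is 1/32 ~ 0.031. Ties count as
exceedances, so p is never 0; Monte-Carlo tests use 10,000 permutations and
p = (1 + #{null >= obs}) / (1 + n_perm). Multiple comparisons use
Benjamini-Hochberg FDR. Null-calibration simulations use 10 blocks
(1024 exhaustive patterns): with 5 blocks the discreteness of the 32-pattern
null makes rejection at alpha = 0.05 conservative by construction (rate
1/32), which says nothing about the engine's validity.

The mixed-effects contract: z-theta ~ eye speed + body speed with a random
intercept per recording channel, REML, predictors standardized; fit
separately per condition. Implemented with `statsmodels` MixedLM.

## Pipeline and problem sizes

A study is one session per synthetic participant; the default mirrors the
real cohort's channel structure (5 participants, channels 4+3+3+3+3 = 16).
Default sessions are 168 s with 8 trials — long enough for several hundred
saccades and stable per-channel estimates while keeping a full study run in
seconds; these scaled-down sizes are a deliberate choice for routine runs
and continuous testing, and all sizes are configurable. Reports are
regenerated bit-identically from config + seed.

## Known limitations

* The generator's theta is a single sinusoidal oscillator; real MTL theta
  is bursty with drifting frequency.
* Condition-specific power locking plus per-interval z-scoring couples the
  two conditions weakly (the locked condition inflates the interval SD),
  which slightly shrinks, but never inflates, the unlocked condition's
  contrast.
* With 5 exchangeability blocks the smallest attainable p is 1/32; real
  studies of this size cannot report p < 0.001 from block-synchronized sign
  flips alone, and the reported `min_attainable_p` makes this explicit.
* Sample-level classification accuracy is capped by one kinematically
  ambiguous sample per event boundary (see above).
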