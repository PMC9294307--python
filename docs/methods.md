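# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the validation experiments behind `cibalance`, in the package's
own words. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Recording protocol emulated

All simulated data follow the study protocol the package targets: 62 cephalic
electrodes (extended 10-20 layout) referenced to the right earlobe, 1000 Hz
sampling, 1000 ms epochs from −200 to 800 ms around each stimulus, stimuli
delivered as 36 ms trains of biphasic electrical pulses at 250 pulses/s at a
rate of 1 Hz, and three stimulation conditions per session: right/first
implant alone (CI1), left/second implant alone (CI2), and bilateral (CIB).
Sensor processing is fixed to: 1–30 Hz zero-phase band-pass (4th-order
Butterworth, forward–backward, chosen to preserve component latencies) →
epoch rejection at ±100 μV between 100 and 800 ms → bad-channel detection →
common average reference over good channels → trial averaging. Visual
screening steps of the original protocol (ocular artifacts, bad channels,
replicability) are replaced by the amplitude rule, the variance-based
channel criteria, and the automated component detector; this is a deliberate
deviation so the pipeline is fully reproducible.

Bad-channel detection judges flatness on the whole recording (variance below
1e−6 μV²) but noisiness on the pre-stimulus baseline only (variance above
10× the median channel baseline variance): the stimulus artifact is huge but
stimulus-locked, and must not masquerade as channel noise.

## Head model and lead fields

A three-shell concentric-sphere conductor replaces template-MRI
boundary-element modelling: radii 80/85/92 mm, conductivities
0.33/0.0042/0.33 S/m (brain/skull/scalp). The dipole potential is expanded
in Legendre harmonics; per-degree radial coefficients are propagated across
shells with 2×2 transfer matrices and closed by the insulating outer
boundary. Radii are scaled by the scalp radius so powers up to the series
truncation (n = 60 by default; the worst-case eccentricity here is
b/R ≈ 0.8, giving residual terms < 1e−6) remain well conditioned. The
implementation is verified against an independently coded homogeneous-sphere
closed-form series (agreement to ~1e−11 relative) and the classic
3·q·cosθ/(4πσR²) pattern of a centred dipole. Electrodes are the standard
10-10 positions projected radially onto the scalp shell. Lead fields are in
μV per nA·m. The volumetric grid is a regular lattice inside the brain shell
(10 mm default spacing, ~1800 voxels; 5 mm approaches the ~64k-voxel regime
but is not needed for the packaged studies). The lead-field interface is a
plain per-voxel matrix, so a BEM solver can be dropped in without touching
the beamformer.

## Beamformer realization

The published description of the time-restricted, coherent-source-suppressing
beamformer leaves the exact constraint set and covariance windows open; the
realization here was decided as follows and validated by the experiments
below.

* **Vector constraints.** Weights per voxel solve
  `min tr(WᵀCW)` s.t. `WᵀL(voxel) = I₃` and `Wᵀa_i = 0` for every null
  pattern `a_i`. A scalar max-output-power variant
  (`orientation="scalar"`) exists for comparison; it was *not* adopted
  because the max-power orientation rotates when a null pattern overlaps the
  local lead field, which biases the moment estimate by tens of percent. The
  vector constraint set keeps the estimate at a voxel bias-protected
  regardless of overlap.
* **Time restriction.** The covariance is estimated from single trials in
  36–400 ms (after the artifact train, covering the response).
* **Residual covariance.** The trial-mean evoked response is subtracted
  before covariance estimation. A covariance containing the phase-locked
  evoked response treats nearby off-grid sources as suppressible
  interference and cancels them in proportion to their strength, which
  inverts between-condition pseudo-Z comparisons (stronger sources lose
  more). With deterministic noiseless data the residual is zero and the raw
  covariance is used instead.
* **Artifact nulls.** Top-k spatial singular vectors of the evoked artifact
  window (0–36 ms); k defaults to the number of stimulated sides.
* **Coherent-source nulls.** Bilateral auditory responses are coherent
  across hemispheres, and a minimum-variance filter cannot suppress a
  coherent source through the covariance. Each hemisphere is therefore imaged
  with the top-3 lead-field singular patterns of the *contralateral*
  auditory ROI added to the null set — a data-independent realization of
  coherent-source suppression. Each hemisphere map covers its own
  hemisphere's voxels and carries its own omnibus threshold.
* **Regularization.** Diagonal loading at 5% of the mean covariance
  eigenvalue.

## Pseudo-Z and the omnibus threshold

Voxel activity is summarised as PZ = ‖mean moment vector over the signal
window‖ / total baseline SD of the moment components, with the baseline fixed
at −200 to −80 ms. The signal window is the detected first-component latency
± 2.5 ms (matching the 5 ms surface-topography convention). Magnitude rather
than signed mean is used (reported PZ values are non-negative). Component
detection runs on the artifact-cleaned evoked (artifact subspace projected
out) because the band-limited artifact residual otherwise appears as the
first post-stimulus GFP peak; the detector takes the earliest GFP local
maximum in 36–250 ms with prominence above 2× the baseline GFP SD, earliest
latency winning ties, and reports an explicit "no component" outcome when
nothing qualifies (such datasets enter the index tables as missing).

The omnibus threshold is the (1−α) quantile (α = 0.05) of the
max-over-voxels PZ computed over all one-sample-step placements of the
signal-window width inside the baseline. Subtracting it from each voxel's PZ
gives the corrected map; positive corrected values mark significant
activation. Empirically the probability of any spurious positive corrected
value under pure noise is ~0.01–0.05 (the overlapping placements make the
procedure slightly conservative); the acceptance suite verifies ≤ 0.07 over
200 noise-only simulations.

## Indices

Peak corrected PZ per hemisphere ROI (left x ≤ −55, right x ≥ 55;
−35 ≤ y ≤ 5; −10 ≤ z ≤ 20 mm), ties broken to the lowest voxel index.
Non-significant peaks are set to exactly 0 before index computation and each
substitution is logged. When both inputs of a ratio index are 0, the index is
undefined and propagates as missing (returning 0 would fabricate symmetry);
missing rows are dropped listwise per model with counts logged. Ratio indices
are clipped to [−100, 100] against floating-point overshoot. Raw bilateral
speech benefit is reported alongside the normalized version; the normalized
benefit is undefined when the opposite ear is at ceiling.

## Synthetic-data generator

The generator is first-class, tested code. Its defaults are the study
conditions where stated and otherwise realistic choices, documented here:

* **Sources.** One dipole per auditory cortex at (±60, −25, 8) mm,
  tangential orientation. Morphologies: mature P1-N1-P2 (Gaussian lobes
  +0.3/−1.0/+0.6 at 70/95/175 ms, σ 8/14/25 ms) for the established ear;
  immature two-lobe N(CI)-P(CI) (−1.0/+0.55 at 97/200 ms, σ 16/30 ms) for
  the newly implanted ear and bilateral stimulation. Lobes have compact
  support (±4σ) and are exactly zero over the baseline.
* **Amplitudes.** A per-hemisphere budget of 120 nA·m split between the two
  ears gives scalp peaks of roughly 5 μV for the mature response and 11 μV
  for the abnormally large immature response, matching the reported
  qualitative picture.
* **Noise.** Independent Gaussian sensor noise, 15 μV per sample per channel
  (single-trial, after band-limiting — a typical evoked-EEG noise floor).
* **Artifact.** Charge-balanced biphasic pulse pairs at 250 pulses/s over
  0–36 ms riding on a baseline pedestal of 0.6 × amplitude (default
  500 μV at the implant-side maximum). The pedestal emulates the amplifier
  baseline shift of real implant stimulation; a perfectly charge-balanced
  train has almost no 1–30 Hz content and would vanish in the filtered
  band, which real artifacts do not. Topography is rank-1, a Gaussian
  (55 mm scale) centred over the implant; bilateral stimulation adds one
  full-amplitude pattern per side.
* **Longitudinal effect structure.** Cortical representation at the cohort
  mean delay is −35% (newly implanted ear dominant) with slope −9% per year
  of inter-implant delay and an 8% between-participant SD — anchored to the
  reported medians (−33.6/−49.4%) and the steep reported delay
  relationship. A left-hemisphere gain excess of 0.25 plants ≈ −25%
  lateralization (the reported first-ear estimated marginal mean is
  −24.5%). Second-implant and bilateral amplitudes decay across sessions
  toward 0.55 of baseline (rate 0.9 per session) while first-implant
  amplitudes stay constant. Bilateral enhancement is planted at +40 nA·m in
  the right and −20 nA·m in the left auditory cortex, mirroring the
  reported large hemisphere asymmetry. Speech scores are binomial
  percent-correct draws.
* Every dataset carries its ground-truth table; all randomness flows through
  one seeded generator per dataset, and identical seeds give bit-identical
  output.

**What the generator does not emulate:** real CI artifacts with latency
jitter, higher spatial rank, or amplifier saturation; induced (non-phase-
locked) oscillatory activity; ocular and movement artifacts (rejection is
tested with injected excursions); volume-conduction errors from non-spherical
anatomy; the online 0.15–100 Hz acquisition filter (simulation targets the
offline-filtered regime). Passing tests therefore demonstrate correctness of
the algorithms under the stated model, not performance on arbitrary clinical
recordings.

**Known limitation.** Nulling an artifact topography that overlaps a
hemisphere's lead fields raises that hemisphere's beamformer noise gain and
lowers its pseudo-Z. Because the artifact side follows the stimulated ear,
per-hemisphere representation values carry a condition-dependent offset in
the simulations (left hemisphere shifted toward first-ear dominance, right
toward second-ear dominance). Pooled quantities — the delay slope and the
enhancement hemisphere contrast — are robust to it, and those are the
planted effects the recovery study scores.

## Mixed models

REML linear mixed models via `statsmodels MixedLM` with a participant random
intercept. Factors use sum-to-zero coding, so Wald F tests of term blocks
are Type-III-like. Denominator degrees of freedom use a between-within
(containment) approximation — a term whose design columns are constant
within every participant is tested against participants minus
between-parameters, all others against residual observations — with the
method label recorded in every table. This is exact for balanced designs;
the suite validates calibration by simulation (null-term rejection rate ≈ α,
95% CI coverage ≥ 90%) and cross-checks fixed effects and variance
components against `lme4` via Rscript. Estimated marginal means average
model predictions over the other factors with covariates at their sample
means; pairwise contrasts use the studentized-range (Tukey) family-wise
adjustment, which reduces to the unadjusted two-sided p for two levels.
Time is treated categorically (four bins: boundaries 21/75/135 days chosen
midway between the reported bin means so that every reported session mean
± SD falls inside its bin; configurable).

## Validation experiments and problem sizes

`cibalance.validation` implements the package's calibration studies; the
acceptance suite and `scripts/acceptance.py` run them at these sizes (chosen
as the package's own desk-scale defaults):

* **Localization**: 50 noiseless single-dipole placements in the auditory
  ROI boxes, 10 mm grid; pass: median peak-to-truth distance ≤ grid spacing.
* **Suppression necessity**: 500 μV rank-1 artifact, three seeds; the
  constrained beamformer's source estimate changes ≤ 10% (median) versus
  the artifact-free run, a conventional scalar LCMV with whole-epoch
  covariance changes ≥ 50%.
* **Omnibus calibration**: 200 noise-only simulations, 20 mm grid, 30
  epochs; pass: any-positive-corrected-PZ rate ≤ 0.07 at α = 0.05.
* **End-to-end recovery**: 12 seeds × (13 participants × 4 sessions × 3
  conditions), 10 mm grid, 36 epochs per condition (a scaled-down epoch
  count; the study-protocol default is 200). Scored per seed: sign of the
  delay coefficient in the representation mixed model, and significance +
  direction of the hemisphere effect on enhancement. Pass: ≥ 95% of seeds
  each. The reproduction script runs 8 seeds for the same rates.
* **Interval coverage**: 100 data-level replicates of the random-intercept
  design; pass: 95% Wald CI covers the planted effect in ≥ 90%.

## External data

The pipeline ingests directories of epoch HDF5 exports (`external_data`) and
marks the run's provenance accordingly; reproducing the original study's
group estimates requires its deposited recordings and is outside the
packaged, network-free scope. Continuous EDF/BrainVision recordings can be
epoched with MNE upstream of the pipeline.
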