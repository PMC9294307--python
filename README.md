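# cibalance

Cortical-balance analysis of sequential bilateral cochlear implantation:
synthetic auditory-evoked EEG with known ground truth, an
artifact-suppressing minimum-variance beamformer with pseudo-Z activation
maps, hemispheric balance indices, and longitudinal linear mixed models.

## The problem

Children with profound bilateral deafness who received one cochlear implant
(CI) early in life and a second implant (CI-2, in the opposite ear) roughly a
decade later develop under strongly asymmetric stimulation. The question is
how the auditory cortices weight the established input (right ear, CI-1), the
newly restored input (left ear, CI-2), and bilateral stimulation over the
first year of bilateral hearing. Answering it from EEG requires solving three
problems at once:

1. **the stimulus artifact** — each trial starts with a 36 ms train of
   biphasic electrical pulses (250 pulses/s, 1 Hz rate) that dwarfs the
   cortical response;
2. **source-level asymmetry measures** — channel-level potentials cannot
   separate left from right auditory cortex; and
3. **small-cohort longitudinal inference** — 13 adolescents, four
   categorical time bins, repeated measures.

`cibalance` implements the full chain for study-protocol data (62 cephalic
channels + right-earlobe reference, 1000 Hz, 1000 ms epochs from −200 to
800 ms) and ships a longitudinal simulator so every stage is testable without
any data download.

## The method

**Beamformer.** Sources are imaged on a volumetric MNI grid with a linearly
constrained minimum-variance (LCMV) vector beamformer with two additions for
electrically stimulated recordings (time-restricted artifact and
coherent-source suppression): the covariance is estimated from single trials
outside the artifact window, and the constraint set couples unit gain at each
voxel with exact zero gain on the artifact's spatial patterns (SVD of the
artifact window) and on the lead-field subspace of the contralateral auditory
cortex (bilateral responses are coherent across hemispheres, so covariance
minimisation alone cannot suppress them):

    min tr(Wᵀ C W)   s.t.   Wᵀ L(voxel) = I₃,   Wᵀ a_i = 0.

**Pseudo-Z.** Voxel activity is the beamformed evoked moment, summarised as
PZ = |mean moment in the component window| / SD of the pre-stimulus baseline
(−200 to −80 ms). An omnibus threshold — the 95th percentile of the
max-over-voxels PZ under resampled baseline windows — is subtracted so
positive corrected values mark activation above baseline brain activity
(type-I rate ≈ 0.01–0.05 by construction, verified by simulation).

**Indices** from the omnibus-corrected peaks of the left (x ≤ −55) and right
(x ≥ 55) auditory ROI boxes (−35 ≤ y ≤ 5, −10 ≤ z ≤ 20 mm), with
non-significant peaks set to exactly 0:

- cortical lateralization (%) = (R_AC − L_AC)/(R_AC + L_AC) × 100
- cortical representation (%) = (right ear − left ear)/(sum) × 100, per hemisphere
- bilateral enhancement = bilateral − ipsilateral-ear unilateral response
- normalized bilateral benefit (%) = (bilateral − opposite ear)/(100 − opposite ear) × 100
  for percent-words-correct speech scores

**Models.** Each index is fit with a REML linear mixed model (fixed: time
bin, condition, hemisphere and interactions; covariates: age at CI-1 and
inter-implant delay; random intercept per participant), with
estimated marginal means, Tukey-corrected pairwise contrasts, and
between-within denominator degrees of freedom.

## Worked example

```python
from cibalance.cohort import packaged_cohort, summarize_cohort
print(summarize_cohort(packaged_cohort()))
```

```
                              mean    sd     n
age_onset_deafness            0.26  0.60  13.0
duration_bilateral_deafness   2.39  1.25  13.0
age_ci1                       2.65  1.10  13.0
age_ci2                      12.72  2.77  13.0
inter_implant_delay          10.07  2.19  13.0
```

The cohort of 13 received the first implant at 2.65 ± 1.10 years and the
second 10.07 ± 2.19 years later. Simulating that cohort end to end (four
sessions × three stimulation conditions each, 10 mm grid, 36 epochs per
condition) and fitting the study models:

```python
from cibalance.pipeline import PipelineConfig, run_pipeline
res = run_pipeline(PipelineConfig(seed=1, grid_mm=10.0, n_epochs=36))
s = res["models"]["summaries"]
```

prints, via the summaries dictionary:

```
enhancement EMMs  : [('left', -0.75), ('right', 3.66)]
hemisphere effect on enhancement: F(1, 69) = 36.3, p = 7.3e-08
delay coefficient (representation model): -12.80 %/year
```

The planted effect structure is recovered: bilateral enhancement is present
in the right auditory cortex and absent in the left (the generator plants
exactly this asymmetry), and a longer inter-implant delay predicts stronger
cortical representation of the newly implanted ear (negative delay
coefficient; the generator plants −9%/year at the source level).

A command-line interface mirrors the library stages:

```bash
cibalance cohort --out summary.csv
cibalance simulate --seed 4 --condition CI2 --n-epochs 200 --out epochs.h5
cibalance localize --epochs epochs.h5 --grid-mm 10 --out peaks.csv
cibalance indices --peaks peaks.csv --out indices.csv
cibalance report --seed 1 --out report/
```

## Layout

```
src/cibalance/
  cohort.py          participant table, summaries, session time bins
  synthetic.py       evoked-EEG generator (waveforms, artifact, cohorts)
  montage.py         62-channel 10-10 layout + earlobe reference
  preprocess.py      filtering, rejection, CAR, averaging, GFP, components
  source_imaging.py  spherical forward model, TRACS beamformer, pseudo-Z
  indices.py         lateralization / representation / enhancement / benefit
  stats.py           mixed models, EMMs, Tukey contrasts, OLS predictors
  pipeline.py        end-to-end orchestration and report bundle
  validation.py      calibration & recovery experiments
  cli.py             command-line interface
```
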