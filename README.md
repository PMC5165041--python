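# mriqa

Automated quality assessment of T1-weighted 3D structural brain MRI.

Artifacts — eye-movement ghosting behind the orbits, motion ringing of the
bright skull fat near the vertex, and wrap-around aliasing that folds the
nose onto the back of the head — silently corrupt morphometric analyses.
Screening thousands of volumes by slice-wise visual inspection is slow and
subjective.  `mriqa` computes objective quality features from each volume
and its tissue-probability maps, and classifies volumes as *usable* or
*not-usable* with a balanced, repeated, cross-validated support vector
machine, so large neuroimaging databases can be triaged automatically.

It is aimed at neuroimaging researchers and database curators who already
run unified segmentation (tissue probability maps and native↔normalized
affine transforms are consumed as inputs; a morphological fallback exists
for volumes without segmentation).

## Features

**Volumetric features** quantify global gray/white contrast:

- `VF1` — 100-bin intensity histogram over `[0, I_max]`;
- `VF2_c` — 100-bin tissue-probability histograms over `[0, 1]` for
  c ∈ {GM, WM, CSF};
- `VF3 = gw_t_score = (μ̂_WM − μ̂_GM) / sqrt(σ̂²_GM + σ̂²_WM)`, the t-like
  contrast between the masked (p ≥ 0.5) gray- and white-matter intensity
  distributions.

**Artifact-specific features** measure signal in the air, where no anatomy
belongs.  A *background-mask* is built by averaging spatially normalized
background probability maps across the cohort, warping the average back to
each native space, and thresholding at 0.5.  Then:

- `ASF1` (eye movement): per axial slice of the *eye-mask* (background in
  front of the eye sockets), the median of positive voxels along y forms a
  noise-vector `I_nv(x)`; `ASF1 = max_z Σ_x I_nv(x, z)`;
- `ASF2` (ringing): on the *ring-mask* (background slab around the upper
  head), the windowed absolute difference
  `|I_nv(x+20) − I_nv(x)| / 20` is summed over x and maximized over slices;
- `ASF3` (aliasing): over 30 midline sagittal slices, each slice is
  collapsed along z into a raw-vector over y; `ASF3 = max_x min_y I_rv(x, y)`.
  A clean air gap behind the head drives the minimum to the noise floor;
  folded-in anatomy raises it.

**Classification** draws a class-balanced subsample, runs stratified
10-fold cross-validation with fold-wise standardization, trains an RBF
SVM, pools fold predictions into accuracy / sensitivity (not-usable
recall) / specificity (usable recall), and repeats the whole procedure
(default 1000×).  A permutation null (training labels shuffled) verifies
results exceed chance, and pairwise two-tailed t-tests compare feature
combinations.

A synthetic head-phantom generator with parametric artifact injection
(`mriqa.phantom`) provides labeled cohorts with ground-truth tissue maps,
so the entire pipeline is testable without scanner data.

## Worked example

```python
import mriqa as m
from mriqa.pipeline import extract_cohort_features

cohort = m.generate_cohort(20, usable_fraction=0.5, seed=8, shape=(62, 64, 64))
frame, labels = extract_cohort_features(cohort)
print(frame[["subject_id", "vf3", "asf1", "asf2", "asf3"]].head(6).round(1))

cfg = m.ExperimentConfig(feature_combination=("ASF1", "ASF2", "ASF3"),
                         n_repeats=20, seed=0)
result = m.train_and_evaluate(frame, labels, cfg)
print({k: round(v["mean"], 1) for k, v in result.summary().items()})
```

prints

```text
subject_id  vf3  asf1  asf2  asf3
   sub-000  9.8  35.4   1.8  50.2
   sub-001  8.3  40.7   1.6  57.0
   sub-002 10.9 183.2   1.7  61.0
   sub-003 10.5  62.5   1.6  73.2
   sub-004 11.6  34.5   1.6  55.5
   sub-005 12.1  70.2   1.4  56.0
{'accuracy': 100.0, 'sensitivity': 100.0, 'specificity': 100.0}
```

`vf3` around 10 reflects healthy gray/white contrast; `asf1`/`asf2`/`asf3`
sit at their noise baselines for clean subjects and rise by one to two
orders of magnitude when the corresponding artifact is injected, which is
why the artifact features alone separate this synthetic cohort perfectly.

The same pipeline is available from the shell:

```sh
mriqa simulate --n 20 --usable-fraction 0.5 --seed 8 --out-dir cohort/
mriqa extract  --in-dir cohort/ --out features.csv
mriqa classify --features features.csv --labels cohort/labels.csv \
               --combination ASF --repeats 100 --out report.json
```

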