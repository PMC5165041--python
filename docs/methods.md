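# Methods

## Coordinate conventions

All volumes use 0-based voxel indices with x = sagittal (left→right),
y = coronal (anterior→posterior), z = axial (inferior→superior).  NIfTI
files are reoriented to this convention on load (canonical RAS+, then a
y-flip), and small negative interpolation overshoots are clamped to zero
with a warning, since the intensity model assumes a `[0, I_max]` range.
Published slice coordinates in this field are 1-based; they are converted
at input boundaries (e.g. a printed midline slice 62 on a 124-slice
acquisition is index 61 internally).

## Feature definitions and numerical choices

**Histograms (VF1, VF2).**  100 bins over `[0, domain_max]`, right-closed:
bin n covers `((n−1)Δ, nΔ]`.  The first bin's lower edge is additionally
closed so exact-zero voxels (air) are counted and the counts always sum to
the voxel count; a strictly half-open first bin would silently drop them.
VF1 uses the volume's own maximum as `domain_max`; VF2 fixes it to 1 so
probability histograms are comparable across subjects and classes.  VF1
includes background voxels, which dominate the first bin — they carry the
noise floor and are informative rather than harmful.

**Contrast score (VF3).**  GM and WM masks are the probability maps
thresholded at 0.5 (closed comparison, so the boundary case is
deterministic).  Two readings of the class statistics exist:

- *intensity* (default): mean/variance of the masked positive voxel
  intensities.  Voxels that are exactly zero inside a mask are treated as
  mask artifacts, not tissue, and excluded.
- *literal*: mean/variance of the 100 histogram bin counts of each masked
  image.  Because the count mean is just (class size)/100, the mean
  difference is independent of contrast; the mode is retained so the two
  readings can be compared, but it is not the default.

Population variances (no Bessel correction) are used throughout; with
~10⁴ voxels per class the distinction is immaterial.

**Noise vectors and ASFs.**  The median of an empty set (a column with no
positive in-mask voxel) is defined as 0, the neutral element for the
downstream sum; even-count medians are midpoints.  Slices where a mask is
empty are skipped in the max — equivalent to treating them as zero
contributions, just cheaper.  The ASF2 difference window defaults to 20
voxels and ASF3 to a 30-slice band (half-width 15) centered on `nx // 2`;
both come from a 124-slice sagittal acquisition geometry and are
configurable (`asf.window`, `asf.midline`, `asf.half_width`).  ASF3's
minimum runs over the full y range: restricting it to the retro-cephalic
region is unnecessary because an empty plane anywhere already floors the
minimum, and the full range keeps the definition parameter-free.

**Masks.**  Probability maps are warped with trilinear interpolation
(clipped back to [0, 1]); the fill value for points outside the source
grid is 1 for background maps and 0 for tissue maps, because beyond the
imaged field of view there is air.  Threshold comparisons are closed
(≥ 0.5).  The eye-mask extends the warped eye-socket boxes along y but
clips each (x, z) column strictly anterior of its first head voxel;
without the clip, the y-projection would also collect background behind
the head.  The ring-mask restricts the background to axial slices
`[z_min + 0.6·(z_max − z_min), z_max − 5]` of the head's z-extent; the
published construction states such bounds exist (below: eye-movement
interference, above: axial wrap) but not their values, so both are
config-exposed (`masks.ring.lower_frac`, `masks.ring.top_margin`).
Eye-socket boxes must be estimated once per normalized template for real
data (`masks.eye_boxes`); shipped defaults match only the phantom
geometry.

## The synthetic phantom

Each subject is an exact affine image of a fixed head template: an
ellipsoidal head with skull/fat shell, subarachnoid CSF rim, GM shell and
WM core, two lateral ventricles, two eye spheres half-embedded in the
anterior face, and a blunt nose running from the head front to the
anterior grid edge.  Default grid 124×128×128 (tests and the acceptance
script use 62×64×64, half-scale, purely to keep desk runtimes low).
Intensities follow the T1 ordering background ≪ CSF < GM < WM < fat/skull
(0, 50, 120, 180, 220, 240 by default) plus Gaussian noise (σ = 3,
clipped at zero).  Ground-truth probability maps keep the air/head
boundary crisp — segmentation is confident about air — while head classes
are softened against each other (σ = 0.7 voxels) and renormalized to a
partition of unity; this is what makes "every ASF is exactly zero on a
clean noise-free phantom" an exact statement rather than a tolerance.

Cohorts add per-subject variability: per-axis head scale (±8%, with the
matching affine registration returned as the transform pair), ventricle
scale (0.8–1.3), per-class contrast jitter (±7%), and noise level
(2.5–3.5).  This variability is what real volumetric features have to see
through; without it any global intensity change would be trivially
detectable and the feature comparison would be meaningless.

**Artifact injection** happens in image space, not k-space: the
background features measure where artifact energy lands, not how it got
there, and image-space injection keeps the support analytically known.

- *Eye movement*: attenuated replicas (weights `0.55^k`, k = 1..6) of the
  eye spheres shifted anteriorly along y.
- *Ringing*: attenuated replicas (gain 0.35) of the upper-third skull/fat
  rim shifted laterally along ±x.
- *Aliasing*: the anterior-most `⌈amp·0.2·ny⌉` coronal planes of object
  signal (receiver noise in the air does not fold) are wrapped to the
  posterior field-of-view edge.  `overlay=False` leaves a clean air gap
  behind the head (the "separated nose" scenario); `overlay=True` lands
  the wrap on the posterior head surface and tiles it to the edge, so no
  clean plane survives.

Replicas and wraps combine with the image by voxelwise **maximum** (the
dominant-magnitude approximation) and the wrapped block is weighted by
amplitude, emulating coil-sensitivity falloff outside the FOV.  Additive
composition would stack artifact signal on already-bright tissue, inflate
`I_max`, rescale every VF1 bin, and make the global histogram an
implausibly strong artifact detector; the maximum keeps artifact energy
in the air, where the ASFs measure it, and leaves `I_max` stable.
Amplitude weighting makes ASF3 respond monotonically instead of as a
step.  Severity labels derive from amplitude cutoffs (none < 0.10 ≤
slight < 0.35 ≤ moderate < 0.65 ≤ heavy); any visible wrap (amp ≥ 0.10)
is assumed to reach the head.

**What the phantom does not emulate:** MR physics (no Bloch simulation,
coil sensitivities or bias fields), anatomical detail (no gyri, sulci or
skull base), k-space-coherent ghosting, or rater disagreement (labels are
deterministic functions of the injected amplitudes).  Passing tests
therefore demonstrate that the features measure what they claim to
measure and that the protocol is sound — not that the classifier's
synthetic accuracies transfer to scanner data.

## Classification protocol

Per repeat: a balanced subsample (all minority-class volumes plus an
equal-size uniform draw of the majority class), stratified 10-fold CV,
per-fold standardization fitted on the training portion only (histogram
counts and ASFs live on wildly different scales), an SVM fit, and pooled
fold predictions.  Both the subsample and the fold assignment are
re-randomized every repeat.  Defaults: RBF kernel, C = 1, kernel width by
the median heuristic on the standardized training features (γ = 1 /
median squared pairwise distance, computed on at most 150 rows); all
config-exposed since the published protocol does not state them.
Sensitivity is not-usable recall, specificity usable recall, and accuracy
is pooled over folds rather than averaged per fold.  Degenerate repeats
(single-class training fold) are redrawn with a warning so the repeat
count stays interpretable.  Histograms enter the SVM as raw counts by
default (`histograms.normalize` divides by row totals).

The permutation null shuffles training labels inside each fold while
test labels stay intact; the p-value uses the add-one estimator
`(1 + #{null ≥ observed}) / (1 + N)` to avoid exact zeros.  Pairwise
combination comparisons use two-sample two-tailed Student t-tests,
reported unadjusted with the conventional p < 0.05 / p < 10⁻³ flags plus
an optional Bonferroni column.  Severity-group contrasts report
group means with standard errors and pairwise t-tests; groups of size one
are marked untestable, absent groups are omitted.

## Problem sizes

Tests and `scripts/acceptance.py` use 62×64×64 phantoms, cohorts of up to
120 subjects, 50–100 protocol repeats, and 100 permutations — scaled-down
but structurally identical versions of the full protocol (1000 repeats,
10,000 permutations), chosen as sensible desk-scale defaults.

## Known limitations

- Only affine native↔normalized transforms are supported; deformation
  fields are out of scope.
- The ring-mask cannot see ringing that stays entirely inside the brain
  (a known blind spot of background-based features).
- Additional artifact families (grainy images, head movement, teeth
  fillings) have no dedicated features; axial- and sagittal-direction
  aliasing are natural extensions of ASF3 but are not implemented.
- The morphological background fallback assumes head-brighter-than-air
  contrast and is undefined on inverted-contrast images (it warns).
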