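# Methods

`gliomap` quantifies where a glioma sits in brain anatomy and evaluates that
signal (alongside conventional radiomics) for molecular and prognostic
classification. This note documents the models, the assumptions behind them,
the tunable parameters, and what the synthetic phantoms do and do not show.

## Tumor-aware parcellation repair

Whole-brain segmenters trained on healthy anatomy mislabel tissue on and
around a glioma: the mass effect deforms structures and the lesion's
appearance has no healthy counterpart. The repair pipeline fills the failed
region by atlas label propagation with cost-function masking:

1. **Mask** the GTV (union of enhancing core, necrotic core and edema) out
   of the subject parcellation.
2. **Rigidly align** the parcellated atlas to the subject. The similarity is
   mean squares on foreground signed-distance maps (SimpleITK backend, full
   sampling so the result is deterministic); if the recovered transform does
   not improve mean per-label Dice over the identity it is discarded.
3. **Mask** the GTV out of the aligned atlas.
4. **Deformably register** the tumor-masked subject segmentation onto the
   tumor-masked atlas. This is a multi-resolution demons registration on
   smoothed label-embedding channels: each label id is mapped to a fixed
   random unit vector in R^8, the one-hot channels are blurred (sigma 1
   voxel), and the demons force is accumulated over channels. Voxels under
   the ignore mask contribute no force, so the field there is purely the
   smooth continuation of the surrounding anatomy (this is the
   cost-function-masking step that makes the method tumor-aware).
5. **Invert** the field by fixed-point iteration (tolerance 0.5 voxel at the
   99th percentile of the composition residual, at most 50 iterations; an
   unmet tolerance raises with the achieved residual).
6. **Warp** the full (unmasked) atlas labels into subject space through the
   composed inverse-deformable + rigid map, nearest-neighbor only. Exact
   half-voxel ties round toward the origin so results are
   platform-independent.
7. **Compose** the repaired parcellation. Default `composite`: subject
   labels outside the GTV, warped-atlas labels inside it (the segmenter is
   trusted where it did not fail). `full_warp` takes the warped atlas
   everywhere. Any in-brain GTV voxel still unlabeled takes its nearest
   non-background label, so the fill contract (no background inside the
   tumor) holds unconditionally.

### Parameters that matter

| parameter | default | why |
|---|---|---|
| `ignore_dilation_mm` | 6 mm | segmenter failures extend *around* the GTV, not only inside it; scoring those voxels would drag the field toward garbage labels. 6 mm covers the failure halo the phantoms emulate (4 mm) plus the label-smoothing support. |
| demons levels / iterations | (4,2,1) / (60,40,20) | coarse levels absorb the bulk displacement; 20 full-resolution sweeps refine boundaries. |
| fluid / elastic smoothing | 1.0 / 1.0 voxel | standard demons regularization; elastic smoothing also diffuses the field into the masked region. |
| step | 2.0 | per-iteration update scale; updates are capped at 1 voxel before smoothing, so larger steps saturate rather than destabilize. |
| embedding channels | 8 | 33 labels embedded in R^8 keep distinct labels nearly orthogonal at an eighth of the one-hot cost. |
| inversion tolerance | 0.5 voxel (p99) | sub-voxel composition error is invisible after nearest-neighbor warping. |

Coordinates: voxel indices are 0-based, physical position = index x spacing
(mm), displacement fields are stored in mm on the fixed grid, mapping
x -> x + u(x).

## Spatial distribution pattern

For the repaired parcellation and the GTV, each of the 32 canonical
structures (14 left/right pairs + CSF, 3rd ventricle, 4th ventricle,
brain-stem) gets

    ratio(s) = |{x : mask_final(x) = s, GTV(x) > 0}| / |{x : mask_final(x) = s}|,

a 32-vector with entries in [0, 1]. The denominator is the structure volume
in the repaired parcellation itself (fixed here for determinism; the
alternative — the tumor-masked parcellation — would make fully-engulfed
structures ill-defined). Structures absent from the parcellation yield 0,
never NaN, and are recorded in a QC flag, so downstream models never see
missing values. Volumes are reported in liters (1 L = 10^6 mm^3).

## Radiomics pool

366 descriptors: 14 shape (computed once — shape is sequence-invariant —
and attributed to T1CE) plus, per sequence (T1, T1CE, T2, FLAIR), 18
first-order and 70 second-order statistics. The 70 texture names are fixed
as data in the manifest: 24 co-occurrence, 16 run-length, 16 size-zone and
14 dependence features; the manifest, not the extractor, owns the list, so
it can be swapped without touching code. Direction-dependent families use
the 13 unique 3D offsets at distance 1 and average the feature value over
directions; size zones use 26-connectivity.

Numerical conventions: discretization defaults to a fixed bin count of 32;
entropies use log2; kurtosis is non-excess (normal = 3); constant ROIs give
zero variance/skewness/kurtosis/entropy; single-level co-occurrence
matrices give correlation-type features the value 1. Mesh volume and
surface area come from a marching-cubes triangulation of the padded binary
ROI; axis lengths are 4*sqrt(eigenvalue) of the physical coordinate
covariance.

## Evaluation protocol

Each model configuration is a single leakage-safe unit fitted per training
fold: min-max rescaling (fit on train, applied unclipped to held-out data;
constant train columns map to 0), SVM-SMOTE oversampling of the minority
class to parity (seeds are the minority-class support vectors of an RBF
SVM; every synthetic row is a convex combination of two real minority
rows), greedy forward feature selection scored by 3-fold inner-CV AUROC
(stop at the cap or at the first step with no strict improvement; ties
break toward the lower column index), then the classifier (random forest or
gradient-boosted trees). The reference harness is 5-fold stratified CV
repeated 10 times over the top-5 grid-search configurations — 250
fold-level observations, reported as mean +/- sd of AUROC, accuracy,
sensitivity and specificity (threshold 0.5). Ensembling is the unweighted
mean of member probabilities. External cohorts are scored with every
parameter frozen.

Label conventions: long-term survivor (OS time >= dataset median, the
median subject counting as long-term), IDH-wildtype, and MGMT-methylated
are the positive classes. The DeLong test compares paired AUROCs via
placement-value covariance; identical scores give p = 1 by convention.

One master seed derives every per-repeat, per-fold, per-member and
per-oversampler stream, so reports are bit-reproducible.

## Synthetic phantoms

The generators emulate exactly the statistical structure the method
assumes, at desk scale:

- **Atlas**: an ellipsoidal brain partitioned by a seeded Voronoi
  tessellation into the 32 canonical structures — 14 pairs mirrored exactly
  across the mid-sagittal plane, 4 midline structures seeded on the plane.
  Only the topology (32 named, paired, contiguous regions) matters to the
  method; the geometry is deliberately schematic.
- **Subjects**: the atlas warped by a random smooth diffeomorphism
  (Gaussian-smoothed noise, RMS amplitude 3 mm, smoothness 10 mm, positive
  Jacobian verified, fixed-point inverse stored), with an implanted tumor
  (nested perturbed ellipsoids: necrotic core inside enhancing core inside
  a 6 mm edema shell, clipped to the brain) and a corrupted segmentation:
  inside the GTV dilated by a 4 mm halo, labels are randomly rewritten
  among CSF, the two dominant cortex/white-matter labels, and background —
  the characteristic failure mode of healthy-anatomy segmenters near
  gliomas. Voxels outside the halo are untouched.
- **Intensities**: a Gaussian mixture conditioned on the deformed labels
  (tumor sub-labels act as three extra classes so the lesion is visible),
  with class means/sds drawn from uniform ranges (defaults 25-225 / 5-25 on
  an arbitrary intensity scale), multiplied by a smooth bias field,
  gamma-transformed, blurred, and downsample/upsampled with linear
  interpolation. The ranges are free parameters; no published values exist
  for them.
- **Tabular cohorts**: standard-normal features with planted
  class-conditional mean shifts (effect size in sd units), exact class
  balance, and recorded planted-column names.

Every generator draws from its own named counter-based stream, so adding a
generator never shifts another's draws, and everything is bit-reproducible
from one seed.

What passing phantom tests shows: the repair pipeline recovers labels a
smooth diffeomorphism moved and a simulated segmenter destroyed, and the ML
protocol is leakage-free and calibrated. What it does not show: performance
under real anatomy (cortical folding, ventricle compression by mass effect,
infiltrative tumor margins), real MRI physics, or real label noise —
clinical conclusions require the clinical cohorts.

## Validation experiment sizes

The built-in experiments (`gliomap.benchmarks`, also run by
`scripts/acceptance.py`) use 20 phantoms at 64^3 / 2 mm for repair
recovery; n = 400 subjects, 32 features, 5 planted, for pipeline
calibration at effect sizes 3 and 0 (1 repeat x 5 folds x 2
members, 25-tree forests — enough observations to pin the mean AUROC while
keeping the experiment in minutes); and a 10 x 5 x 5 run on a small cohort
to exercise the 250-observation contract. These sizes are the package's
own choices for routine validation; the protocol constants (10 repeats, 5
folds, 5 models, caps 5/10/10) are fixed in `CVPlan` and the config
surface.

## Known limitations

- The demons similarity operates on label embeddings, not intensities; it
  needs a parcellation on both sides and cannot refine boundaries inside
  homogeneous regions.
- The field inside the GTV is regularizer extrapolation; nothing can
  recover deformation detail smaller than the tumor that left no trace
  outside it.
- The 70-name texture list is one defensible IBSI-family selection; other
  selections of the same families are drop-in manifest replacements.
- SVM-SMOTE interpolates only between minority rows; it never extrapolates
  beyond the minority convex hull.
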