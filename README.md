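# gliomap

Tumor-aware brain parcellation repair and glioma prognosis modeling.

## The problem

Whole-brain segmenters parcellate an MRI into named anatomical structures,
but they are trained on healthy anatomy and fail on and around gliomas —
over-segmenting CSF and mislabeling cortex and white matter exactly where a
neuro-oncologist needs labels most. `gliomap` repairs those failures and
turns the result into a compact, interpretable feature map: for each of 32
brain structures (14 left/right pairs plus CSF, 3rd ventricle, 4th
ventricle and brain-stem), the fraction of that structure's volume occupied
by the gross tumor volume (GTV),

    ratio(s) = |{x : mask_final(x) = s, GTV(x) > 0}| / |{x : mask_final(x) = s}| ∈ [0, 1],

the **spatial distribution pattern** — a 32-vector per subject. The package
is for researchers studying imaging biomarkers of glioma genotype (MGMT
methylation, IDH mutation) and overall survival, and for anyone who needs
anatomically valid parcellations of tumor-bearing brains.

## The method

1. Mask the GTV (enhancing + necrotic + edema) out of the failed subject
   parcellation and out of a rigidly pre-aligned parcellated atlas.
2. Deformably register the masked subject onto the masked atlas with the
   tumor region excluded from the similarity term (cost-function masking),
   so the estimated field φ is driven only by trustworthy anatomy.
3. Warp the full atlas labels into subject space through φ⁻¹: the tumor
   region inherits anatomically coherent labels from its surroundings.

Around this core the package provides synthetic phantom generation
(parcellated brains, implanted multi-compartment tumors, diffeomorphic
deformations, label-conditioned generative MRI intensities, simulated
segmenter failure), a 366-descriptor radiomics pool (14 shape + per
sequence 18 first-order + 70 texture features over T1/T1CE/T2/FLAIR), and a
leakage-safe evaluation protocol: min-max rescaling, SVM-SMOTE, forward
feature selection and classifier fitted per training fold, 5-fold CV
repeated 10× over the top-5 grid-search models (250 observations),
unweighted-mean ensembling, frozen cross-dataset testing, and DeLong paired
AUROC comparison. See `docs/methods.md` for the details and assumptions.

## Worked example

```python
import numpy as np
from gliomap import make_atlas_labels, make_phantom_subject, fill_tumor_labels
from gliomap.spatial import occupancy_ratios

atlas = make_atlas_labels(shape=(64, 64, 64), spacing=(2, 2, 2), seed=0)
subject = make_phantom_subject(atlas, seed=1, with_intensities=False)

tumor = subject.gtv.union()
truth = subject.truth_labels.grid
corrupted = subject.corrupted_labels.grid
print(f"in-tumor label accuracy before repair: "
      f"{(corrupted[tumor] == truth[tumor]).mean():.3f}")

case = fill_tumor_labels(subject.corrupted_labels, atlas, subject.gtv)
repaired = case.mask_final.grid
print(f"in-tumor label accuracy after repair:  "
      f"{(repaired[tumor] == truth[tumor]).mean():.3f}")

vec = occupancy_ratios(case.mask_final, subject.gtv, subject_id="sub-001")
top = vec.as_series().sort_values(ascending=False).head(5)
print("\nmost affected structures (occupancy ratio):")
print(top.to_string(float_format="%.3f"))
```

Output:

```
in-tumor label accuracy before repair: 0.095
in-tumor label accuracy after repair:  0.883

most affected structures (occupancy ratio):
R pallidum                     0.642
R inferior lateral ventricle   0.409
L pallidum                     0.150
L inferior lateral ventricle   0.071
brain-stem                     0.004
```

The phantom's simulated segmenter destroyed 90% of the labels inside the
tumor; the repair recovers 88% of them, and the resulting occupancy vector
says this tumor sits in the right deep gray matter, engulfing two-thirds of
the right pallidum and ~40% of the right inferior lateral ventricle, with
edema reaching the contralateral side.

A command-line surface mirrors the library
(`gliomap phantom | parcellate | features | train | evaluate | compare-auc | run`);
`gliomap run --n-subjects 12 --out run/` executes the whole chain on a
fresh phantom cohort and writes `features.csv`, `cv_observations.csv` and
`metrics.json` into the run directory.

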