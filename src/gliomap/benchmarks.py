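"""Self-contained validation experiments on synthetic phantoms and cohorts.

These are the package's own end-to-end checks: label-repair recovery on
seeded phantoms, calibration of the full ML protocol at planted and null
effect sizes, the leakage sentinel, and the observation-count contract of
the repeated-CV harness. Problem sizes are chosen so each experiment runs
in minutes on one CPU; the quantities they report are recomputed from
scratch on every call.
"""

from __future__ import annotations

import numpy as np

from .ml import CVPlan, GliomaModel, evaluate, repeated_cv
from .parcellation import RepairConfig, fill_tumor_labels
from .phantom import make_atlas_labels, make_ml_cohort, make_phantom_subject


def _in_gtv_dice(mask_final, truth, gtv_mask) -> float:
    """Mean per-structure Dice restricted to the GTV."""
    labs = [l for l in np.unique(truth[gtv_mask]) if l != 0]
    scores = []
    for lab in labs:
        a = (mask_final == lab) & gtv_mask
        b = (truth == lab) & gtv_mask
        denom = a.sum() + b.sum()
        if denom:
            scores.append(2.0 * (a & b).sum() / denom)
    return float(np.mean(scores)) if scores else 0.0


def parcellation_recovery(
    n_phantoms: int = 20,
    shape=(64, 64, 64),
    spacing=(2.0, 2.0, 2.0),
    amplitude: float = 3.0,
    seed: int = 0,
) -> dict:
    """Repair corrupted phantom parcellations and score against ground truth.

    For each phantom: in-GTV label accuracy before/after repair, mean
    per-structure in-GTV Dice, and the median voxel residual between the
    estimated inverse field and the generating field over the brain.
    """
    atlas = make_atlas_labels(shape, spacing, seed=seed)
    acc_before, acc_after, dices, residuals = [], [], [], []
    for i in range(n_phantoms):
        subj = make_phantom_subject(atlas, seed=seed * 1000 + i + 1,
                                    amplitude=amplitude, with_intensities=False)
        tumor = subj.gtv.union()
        truth = subj.truth_labels.grid
        case = fill_tumor_labels(subj.corrupted_labels, atlas, subj.gtv, RepairConfig())
        acc_before.append(float((subj.corrupted_labels.grid[tumor] == truth[tumor]).mean()))
        acc_after.append(float((case.mask_final.grid[tumor] == truth[tumor]).mean()))
        dices.append(_in_gtv_dice(case.mask_final.grid, truth, tumor))
        res_vox = np.linalg.norm(
            (case.field.inverse - subj.true_field.displacements) / np.asarray(spacing), axis=-1
        )
        residuals.append(float(np.median(res_vox[truth > 0])))
    return {
        "n_phantoms": n_phantoms,
        "n_improved": int(sum(a > b for a, b in zip(acc_after, acc_before))),
        "accuracy_before": acc_before,
        "accuracy_after": acc_after,
        "mean_in_gtv_dice": float(np.mean(dices)),
        "per_phantom_dice": dices,
        "median_field_residual_vox": float(np.median(residuals)),
        "per_phantom_residual_vox": residuals,
    }


def _calibration_members(seed: int, n_members: int = 2):
    return [
        GliomaModel(family="rf", model_params={"n_estimators": 25}, ffs_cap=5,
                    inner_folds=3, random_state=seed + m)
        for m in range(n_members)
    ]


def pipeline_calibration(effect_size: float, seed: int = 0, n_subjects: int = 400) -> dict:
    """Full protocol (min-max, SVM-SMOTE, FFS, RF) on a planted cohort.

    At a strong planted effect the CV AUROC should approach 1 and forward
    selection should pick only planted columns; at zero effect the AUROC
    should sit at chance (type-I control of the whole pipeline).
    """
    df = make_ml_cohort(n_subjects=n_subjects, n_spatial=32, n_radiomic=0,
                        n_informative=5, effect_size=effect_size, seed=seed)
    cols = list(df.columns[1:-1])
    X = df[cols].to_numpy()
    y = df["label"].to_numpy()
    report = repeated_cv(X, y, _calibration_members(seed), CVPlan(n_repeats=1, k=5, seed=seed))

    planted = set(df.attrs["informative"])
    model = _calibration_members(seed, 1)[0].fit(X, y)
    selected = [cols[j] for j in model.selector_.selected_]  # in addition order
    precision = len(set(selected) & planted) / len(selected) if selected else 0.0
    return {
        "auroc": float(report.observations["auroc"].mean()),
        "n_observations": report.n_observations,
        "ffs_selected": selected,
        "ffs_first_planted": bool(selected) and selected[0] in planted,
        "ffs_planted_precision": float(precision),
    }


def leakage_sentinel(seed: int = 0, n_subjects: int = 90) -> dict:
    """AUROC of a sentinel feature that copies the label on validation rows only.

    If any preprocessing or fitting stage peeked at validation data the
    sentinel would score near 1; leakage-free pipelines score near 0.5.
    """
    from sklearn.model_selection import StratifiedKFold

    rng = np.random.default_rng(seed)
    y = rng.permutation(np.r_[np.ones(n_subjects // 2), np.zeros(n_subjects - n_subjects // 2)]).astype(int)
    noise = rng.normal(size=(n_subjects, 4))
    plan = CVPlan(n_repeats=2, k=3, seed=seed)
    aurocs = []
    for rep in range(plan.n_repeats):
        cv = StratifiedKFold(plan.k, shuffle=True, random_state=plan.repeat_seed(rep))
        for fold, (tr, va) in enumerate(cv.split(noise, y)):
            sentinel = rng.normal(size=n_subjects)
            sentinel[va] = y[va]
            X = np.column_stack([sentinel, noise])
            model = GliomaModel(family="rf", model_params={"n_estimators": 15}, ffs_cap=2,
                                inner_folds=2, random_state=fold).fit(X[tr], y[tr])
            aurocs.append(evaluate(model.predict_proba(X[va])[:, 1], y[va])["auroc"])
    return {"sentinel_auroc": float(np.mean(aurocs)), "n_observations": len(aurocs)}


def cv_observation_count(seed: int = 0) -> int:
    """Observation count of the reference plan: 10 repeats x 5 folds x 5 models."""
    df = make_ml_cohort(n_subjects=60, n_spatial=5, n_radiomic=0, n_informative=2,
                        effect_size=1.5, seed=seed)
    X = df.drop(columns=["subject_id", "label"]).to_numpy()
    y = df["label"].to_numpy()
    members = [
        GliomaModel(family="rf", model_params={"n_estimators": 10}, ffs_cap=2,
                    inner_folds=2, random_state=m)
        for m in range(5)
    ]
    report = repeated_cv(X, y, members, CVPlan(n_repeats=10, k=5, seed=seed))
    return report.n_observations
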