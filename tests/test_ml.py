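"""Label construction, preprocessing, selection, CV harness and statistics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression

from gliomap.ml import (
    CVPlan,
    GliomaModel,
    SVMSMOTE,
    TopKEnsembleClassifier,
    binarize_idh,
    binarize_mgmt,
    binarize_os,
    calibration_curve,
    cross_dataset_eval,
    delong_test,
    ensemble_predict,
    evaluate,
    forward_select,
    grid_search,
    minmax_apply,
    minmax_fit,
    repeated_cv,
    svm_smote,
)
from gliomap.phantom import make_ml_cohort

FAST_RF = {"n_estimators": 15}


def _fast_members(n=2, cap=2):
    return [
        GliomaModel(family="rf", model_params=FAST_RF, ffs_cap=cap, inner_folds=2, random_state=i)
        for i in range(n)
    ]


class TestLabels:
    def test_median_split_even(self):
        labels, known = binarize_os([10, 20, 30, 40])
        np.testing.assert_array_equal(labels, [0, 0, 1, 1])
        assert known.all()

    def test_median_subject_is_long_term(self):
        labels, _ = binarize_os([1, 2, 3])
        np.testing.assert_array_equal(labels, [0, 1, 1])

    def test_unknown_times_excluded(self):
        labels, known = binarize_os([10, np.nan, 30, 40])
        np.testing.assert_array_equal(known, [True, False, True, True])

    def test_near_balance_across_seeds(self, rng):
        for _ in range(10):
            t = rng.permutation(rng.uniform(1, 100, size=51))
            labels, known = binarize_os(t)
            assert abs(labels[known].sum() - (len(t) - labels[known].sum())) <= 1

    def test_idh_wildtype_vs_rest(self):
        labels, known = binarize_idh(["wildtype", "mutated", "NOS/NEC", "negative", "unknown"])
        np.testing.assert_array_equal(labels[known], [1, 0, 0, 0])
        np.testing.assert_array_equal(known, [True, True, True, True, False])

    def test_idh_vocabulary_enforced(self):
        with pytest.raises(ValueError, match="unrecognized"):
            binarize_idh(["wild-type"])

    def test_mgmt(self):
        labels, known = binarize_mgmt(["methylated", "unmethylated", "unknown"])
        np.testing.assert_array_equal(labels[known], [1, 0])


class TestMinMax:
    def test_train_maps_to_unit_interval(self):
        state = minmax_fit(np.array([[2.0], [4.0], [6.0]]))
        out = minmax_apply(state, np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_extrapolation_not_clipped(self):
        state = minmax_fit(np.array([[2.0], [6.0]]))
        assert minmax_apply(state, np.array([[8.0]]))[0, 0] == pytest.approx(1.5)

    def test_constant_column_maps_to_zero(self):
        state = minmax_fit(np.array([[3.0, 1.0], [3.0, 2.0]]))
        out = minmax_apply(state, np.array([[3.0, 1.5], [99.0, 2.0]]))
        assert out[0, 0] == 0.0

    def test_round_trip(self, rng):
        X = rng.normal(size=(20, 5))
        state = minmax_fit(X)
        back = state.inverse_transform(minmax_apply(state, X))
        np.testing.assert_allclose(back, X, atol=1e-12)


class TestSVMSMOTE:
    def _imbalanced(self, rng, n_min=10, n_maj=40, p=4):
        X = np.vstack([rng.normal(2, 1, size=(n_min, p)), rng.normal(0, 1, size=(n_maj, p))])
        y = np.r_[np.ones(n_min), np.zeros(n_maj)].astype(int)
        return X, y

    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        Xo, yo = svm_smote(X, y, seed=0)
        np.testing.assert_array_equal(Xo, X)
        np.testing.assert_array_equal(yo, y)

    def test_parity_after_resampling(self, rng):
        X, y = self._imbalanced(rng)
        _, yo = svm_smote(X, y, seed=1)
        counts = np.bincount(yo)
        assert counts[0] == counts[1]

    def test_synthetic_rows_are_convex_combinations(self, rng):
        """Each synthetic sample lies on a segment between two real minority
        rows, checked coordinate-wise via the interpolation parameter."""
        X, y = self._imbalanced(rng)
        Xo, yo = svm_smote(X, y, seed=2)
        X_min = X[y == 1]
        for row in Xo[len(X):]:
            found = False
            for a in range(len(X_min)):
                for b in range(len(X_min)):
                    if a == b:
                        continue
                    d = X_min[b] - X_min[a]
                    nz = np.abs(d) > 1e-12
                    if not nz.any():
                        continue
                    t = (row - X_min[a])[nz] / d[nz]
                    if np.allclose(t, t[0], atol=1e-8) and -1e-9 <= t[0] <= 1 + 1e-9:
                        if np.allclose(row[~nz], X_min[a][~nz], atol=1e-9):
                            found = True
                            break
                if found:
                    break
            assert found

    def test_deterministic(self, rng):
        X, y = self._imbalanced(rng)
        a = svm_smote(X, y, seed=7)
        b = svm_smote(X, y, seed=7)
        np.testing.assert_array_equal(a[0], b[0])

    def test_tiny_minority_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.r_[np.ones(1), np.zeros(9)].astype(int)
        with pytest.raises(ValueError, match="minority"):
            svm_smote(X, y, seed=0)


class TestForwardSelection:
    def test_planted_feature_selected_first(self):
        df = make_ml_cohort(n_subjects=200, n_spatial=10, n_informative=1, effect_size=3.0, seed=3)
        X = df.drop(columns=["subject_id", "label"]).to_numpy()
        y = df["label"].to_numpy()
        planted = list(df.columns[1:-1]).index(df.attrs["informative"][0])
        sel = forward_select(X, y, LogisticRegression(max_iter=200), cap=3, seed=0)
        assert sel[0] == planted

    def test_cap_one_equals_brute_force_best(self, rng):
        from sklearn.metrics import roc_auc_score
        from sklearn.model_selection import StratifiedKFold

        df = make_ml_cohort(n_subjects=150, n_spatial=8, n_informative=2, effect_size=1.5, seed=4)
        X = df.drop(columns=["subject_id", "label"]).to_numpy()
        y = df["label"].to_numpy()
        est = LogisticRegression(max_iter=200)
        sel = forward_select(X, y, est, cap=1, inner_folds=3, seed=5)
        # exhaustive single-feature search with the same folds
        from gliomap.ml.selection import ForwardFeatureSelector

        folds = list(StratifiedKFold(3, shuffle=True, random_state=5).split(X, y))
        scores = []
        for j in range(X.shape[1]):
            per_fold = []
            for tr, va in folds:
                m = clone(est).fit(X[np.ix_(tr, [j])], y[tr])
                per_fold.append(roc_auc_score(y[va], m.predict_proba(X[np.ix_(va, [j])])[:, 1]))
            scores.append(np.mean(per_fold))
        assert sel == [int(np.argmax(scores))]

    def test_all_noise_stops_early_in_majority_of_seeds(self):
        stops = 0
        for seed in range(5):
            df = make_ml_cohort(n_subjects=80, n_spatial=8, n_informative=0,
                                effect_size=0.0, seed=seed)
            X = df.drop(columns=["subject_id", "label"]).to_numpy()
            y = df["label"].to_numpy()
            sel = forward_select(X, y, LogisticRegression(max_iter=200), cap=6, seed=seed)
            stops += len(sel) < 6
        assert stops >= 3


class TestGridSearch:
    def test_singleton_grid_ranks_first(self):
        df = make_ml_cohort(n_subjects=60, n_spatial=5, n_informative=1, effect_size=2.0, seed=0)
        X = df.drop(columns=["subject_id", "label"]).to_numpy()
        y = df["label"].to_numpy()
        ranked = grid_search([("rf", FAST_RF)], X, y, seed=0)
        assert len(ranked) == 1 and ranked.loc[0, "family"] == "rf"

    def test_degenerate_config_never_first_on_separable_data(self):
        df = make_ml_cohort(n_subjects=120, n_spatial=6, n_informative=3, effect_size=3.0, seed=1)
        X = df.drop(columns=["subject_id", "label"]).to_numpy()
        y = df["label"].to_numpy()
        grid = [("rf", {"n_estimators": 1, "max_depth": 1}), ("rf", {"n_estimators": 40})]
        ranked = grid_search(grid, X, y, seed=2)
        assert ranked.loc[0, "params"]["n_estimators"] == 40

    def test_ranking_deterministic(self):
        df = make_ml_cohort(n_subjects=60, n_spatial=5, n_informative=1, effect_size=1.0, seed=2)
        X = df.drop(columns=["subject_id", "label"]).to_numpy()
        y = df["label"].to_numpy()
        grid = [("rf", FAST_RF), ("xgb", {"n_estimators": 20})]
        a = grid_search(grid, X, y, seed=3)
        b = grid_search(grid, X, y, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestRepeatedCV:
    def _data(self, n=60, seed=0, effect=2.0):
        df = make_ml_cohort(n_subjects=n, n_spatial=6, n_informative=2, effect_size=effect, seed=seed)
        return df.drop(columns=["subject_id", "label"]).to_numpy(), df["label"].to_numpy()

    def test_observation_count(self):
        X, y = self._data()
        rep = repeated_cv(X, y, _fast_members(2), CVPlan(n_repeats=2, k=3, seed=0))
        assert rep.n_observations == 2 * 3 * 2

    def test_deterministic(self):
        X, y = self._data()
        plan = CVPlan(n_repeats=1, k=3, seed=4)
        a = repeated_cv(X, y, _fast_members(1), plan)
        b = repeated_cv(X, y, _fast_members(1), plan)
        pd.testing.assert_frame_equal(a.observations, b.observations)

    def test_aggregate_recomputable_from_observations(self):
        X, y = self._data()
        rep = repeated_cv(X, y, _fast_members(1), CVPlan(n_repeats=1, k=3, seed=1))
        agg = rep.aggregate()
        assert agg.loc["auroc", "mean"] == pytest.approx(rep.observations["auroc"].mean())
        assert agg.loc["auroc", "n"] == rep.n_observations

    def test_leakage_sentinel(self, rng):
        """A label-copy feature gives AUROC 1; the same feature informative
        only on validation rows gives chance — preprocessing and training
        never see validation data."""
        n = 90
        y = rng.permutation(np.r_[np.ones(45), np.zeros(45)]).astype(int)
        noise = rng.normal(size=(n, 4))

        X_leaky = np.column_stack([y.astype(float), noise])
        rep = repeated_cv(X_leaky, y, _fast_members(1, cap=1), CVPlan(n_repeats=1, k=3, seed=0))
        assert rep.observations["auroc"].mean() > 0.99

        plan = CVPlan(n_repeats=2, k=3, seed=0)
        # sentinel: equals the label, but only on rows NOT seen in training
        from sklearn.model_selection import StratifiedKFold

        aurocs = []
        for rep_i in range(plan.n_repeats):
            cv = StratifiedKFold(plan.k, shuffle=True, random_state=plan.repeat_seed(rep_i))
            for fold, (tr, va) in enumerate(cv.split(noise, y)):
                sentinel = rng.normal(size=n)
                sentinel[va] = y[va]  # informative only where fitting must not look
                Xs = np.column_stack([sentinel, noise])
                model = GliomaModel(family="rf", model_params=FAST_RF, ffs_cap=2,
                                    inner_folds=2, random_state=fold).fit(Xs[tr], y[tr])
                from gliomap.ml import evaluate as ev

                aurocs.append(ev(model.predict_proba(Xs[va])[:, 1], y[va])["auroc"])
        assert 0.3 < np.mean(aurocs) < 0.7

    def test_lost_class_raises(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        y = np.r_[np.ones(9), np.zeros(1)].astype(int)
        with pytest.raises(ValueError):
            repeated_cv(X, y, _fast_members(1), CVPlan(n_repeats=1, k=3, seed=0))


class TestEnsemble:
    def test_identical_members_equal_single(self):
        df = make_ml_cohort(n_subjects=60, n_spatial=4, n_informative=1, effect_size=2.0, seed=6)
        X = df.drop(columns=["subject_id", "label"]).to_numpy()
        y = df["label"].to_numpy()
        proto = GliomaModel(family="rf", model_params=FAST_RF, ffs_cap=None, random_state=0)
        ens = TopKEnsembleClassifier([clone(proto) for _ in range(5)]).fit(X, y)
        single = clone(proto).fit(X, y)
        np.testing.assert_allclose(ensemble_predict(ens, X), single.predict_proba(X)[:, 1])

    def test_mean_aggregation_arithmetic(self):
        class Fixed:
            def __init__(self, p):
                self.p = p
            def fit(self, X, y):
                return self
            def get_params(self, deep=True):
                return {"p": self.p}
            def set_params(self, **kw):
                return self
            def predict_proba(self, X):
                return np.column_stack([1 - np.full(len(X), self.p), np.full(len(X), self.p)])

        ens = TopKEnsembleClassifier([Fixed(p) for p in (0.2, 0.4, 0.6, 0.8, 1.0)])
        ens.fit(np.zeros((4, 2)), np.array([0, 1, 0, 1]))
        np.testing.assert_allclose(ensemble_predict(ens, np.zeros((3, 2))), 0.6)

    def test_ensemble_not_worse_than_weakest_member(self):
        from gliomap.ml import evaluate as ev

        for seed in range(3):
            df = make_ml_cohort(n_subjects=120, n_spatial=6, n_informative=2,
                                effect_size=1.0, seed=seed)
            X = df.drop(columns=["subject_id", "label"]).to_numpy()
            y = df["label"].to_numpy()
            tr, te = np.arange(0, 80), np.arange(80, 120)
            members = [GliomaModel(family="rf", model_params=FAST_RF, ffs_cap=None,
                                   random_state=i) for i in range(3)]
            ens = TopKEnsembleClassifier(members).fit(X[tr], y[tr])
            member_aucs = [ev(m.predict_proba(X[te])[:, 1], y[te])["auroc"] for m in ens.members_]
            ens_auc = ev(ensemble_predict(ens, X[te]), y[te])["auroc"]
            assert ens_auc >= min(member_aucs) - 1e-9


class TestEvaluate:
    def test_perfect_separation(self):
        m = evaluate([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m["auroc"] == 1.0 and m["accuracy"] == 1.0

    def test_all_ties_give_half(self):
        m = evaluate([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert m["auroc"] == 0.5

    def test_pairwise_count_oracle(self, rng):
        scores = rng.random(6)
        labels = np.array([1, 0, 1, 0, 1, 0])
        m = evaluate(scores, labels)
        wins = 0.0
        pairs = 0
        for i in np.flatnonzero(labels == 1):
            for j in np.flatnonzero(labels == 0):
                pairs += 1
                if scores[i] > scores[j]:
                    wins += 1
                elif scores[i] == scores[j]:
                    wins += 0.5
        assert m["auroc"] == pytest.approx(wins / pairs, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate([0.1, 0.9], [1, 1])

    def test_sensitivity_specificity_threshold(self):
        m = evaluate([0.6, 0.4, 0.6, 0.4], [1, 1, 0, 0])
        assert m["sensitivity"] == 0.5 and m["specificity"] == 0.5


class TestCalibration:
    def test_counts_sum_to_n(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        _, _, counts = calibration_curve(scores, labels, n_bins=10)
        assert counts.sum() == 100

    def test_single_bin_when_scores_cluster(self):
        ms, obs, counts = calibration_curve([0.55, 0.56, 0.57], [1, 0, 1], n_bins=10)
        assert len(ms) == 1 and counts[0] == 3

    def test_calibrated_scores_track_diagonal(self, rng):
        n = 20000
        scores = rng.random(n)
        labels = (rng.random(n) < scores).astype(int)
        ms, obs, counts = calibration_curve(scores, labels, n_bins=10)
        assert np.max(np.abs(ms - obs)) < 0.05

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve([0.5], [1], n_bins=1)


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        s = rng.random(20)
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        res = delong_test(s, s, y)
        assert res.difference == 0.0 and res.p_value == 1.0

    def test_antisymmetry(self, rng):
        a, b = rng.random(30), rng.random(30)
        y = rng.permutation(np.r_[np.ones(15), np.zeros(15)]).astype(int)
        r1 = delong_test(a, b, y)
        r2 = delong_test(b, a, y)
        assert r1.difference == pytest.approx(-r2.difference)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_variance_matches_placement_oracle(self, rng):
        """4+4 toy: covariance of placement values computed by explicit
        loops equals the vectorized implementation."""
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        a, b = rng.random(8), rng.random(8)
        res = delong_test(a, b, y)

        def psi(x, w):
            return 1.0 if x > w else (0.5 if x == w else 0.0)

        def components(s):
            pos, neg = s[y == 1], s[y == 0]
            v10 = [np.mean([psi(p, q) for q in neg]) for p in pos]
            v01 = [np.mean([psi(p, q) for p in pos]) for q in neg]
            return np.array(v10), np.array(v01)

        va10, va01 = components(a)
        vb10, vb01 = components(b)
        auc_a, auc_b = va10.mean(), vb10.mean()
        m, n = 4, 4

        def cov(u, v):
            return ((u - u.mean()) * (v - v.mean())).sum() / (len(u) - 1)

        var = (
            cov(va10, va10) / m + cov(vb10, vb10) / m - 2 * cov(va10, vb10) / m
            + cov(va01, va01) / n + cov(vb01, vb01) / n - 2 * cov(va01, vb01) / n
        )
        assert res.auc1 == pytest.approx(auc_a, abs=1e-12)
        assert res.auc2 == pytest.approx(auc_b, abs=1e-12)
        assert res.variance == pytest.approx(var, abs=1e-12)

    def test_auc_equals_mann_whitney(self, rng):
        s = rng.random(40)
        y = rng.permutation(np.r_[np.ones(20), np.zeros(20)]).astype(int)
        res = delong_test(s, rng.random(40), y)
        assert res.auc1 == pytest.approx(evaluate(s, y)["auroc"], abs=1e-12)


class TestCrossDataset:
    def test_frozen_model_consistency(self):
        df = make_ml_cohort(n_subjects=80, n_spatial=5, n_informative=2, effect_size=2.0, seed=9)
        X = df.drop(columns=["subject_id", "label"]).to_numpy()
        y = df["label"].to_numpy()
        ens = TopKEnsembleClassifier(_fast_members(2, cap=None)).fit(X, y)
        internal = evaluate(ensemble_predict(ens, X), y)
        external = cross_dataset_eval(ens, X, y)
        assert external == internal

    def test_domain_shift_degrades_auroc(self):
        df = make_ml_cohort(n_subjects=200, n_spatial=6, n_informative=3, effect_size=1.5, seed=10)
        X = df.drop(columns=["subject_id", "label"]).to_numpy()
        y = df["label"].to_numpy()
        ens = TopKEnsembleClassifier(_fast_members(2, cap=None)).fit(X[:120], y[:120])
        control = cross_dataset_eval(ens, X[120:], y[120:])["auroc"]
        shifted = cross_dataset_eval(ens, X[120:] * 2.0 + 1.0, y[120:])["auroc"]
        assert shifted <= control + 0.05

    def test_parameters_frozen_during_eval(self):
        import pickle

        df = make_ml_cohort(n_subjects=60, n_spatial=4, n_informative=1, effect_size=2.0, seed=11)
        X = df.drop(columns=["subject_id", "label"]).to_numpy()
        y = df["label"].to_numpy()
        ens = TopKEnsembleClassifier(_fast_members(1, cap=None)).fit(X, y)
        before = pickle.dumps(ens)
        cross_dataset_eval(ens, X, y)
        assert pickle.dumps(ens) == before

    def test_missing_columns_named(self):
        df = make_ml_cohort(n_subjects=60, n_spatial=4, n_informative=1, effect_size=2.0, seed=12)
        X = df.drop(columns=["subject_id", "label"]).to_numpy()
        y = df["label"].to_numpy()
        ens = TopKEnsembleClassifier(_fast_members(1, cap=None)).fit(X, y)
        with pytest.raises(ValueError, match="spatial_03"):
            cross_dataset_eval(
                ens, X[:, :3], y,
                feature_names=["spatial_00", "spatial_01", "spatial_02"],
                trained_feature_names=["spatial_00", "spatial_01", "spatial_02", "spatial_03"],
            )
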