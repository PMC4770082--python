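"""SVM viability classification: curves, tuning, CV discipline, selection."""

import numpy as np
import pandas as pd
import pytest

from embryomech import CohortSpec, cohort_to_frame, sample_cohort
from embryomech.classify import (
    SELECTION_GRID,
    TrainedClassifier,
    combine_features,
    feature_matrix,
    forward_feature_select,
    mc_cross_validate,
    operating_points,
    roc_pr_curves,
    tune_hyperparams,
)


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise oracle: P(s+ > s-) + 0.5 P(s+ = s-)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


class TestRocPrCurves:
    @pytest.mark.parametrize("seed,tied", [(0, False), (1, True), (2, True)])
    def test_auc_equals_pairwise_oracle_exactly(self, seed, tied):
        rng = np.random.default_rng(seed)
        n = 200
        labels = rng.random(n) < 0.4
        scores = rng.normal(labels.astype(float), 1.0)
        if tied:
            scores = np.round(scores)  # heavy ties
        ev = roc_pr_curves(scores, labels)
        assert abs(ev.auc_roc - mann_whitney_auc(scores, labels.astype(int))) < 1e-12

    def test_perfect_scores_give_unit_auc(self):
        labels = np.r_[np.zeros(5), np.ones(5)].astype(int)
        ev = roc_pr_curves(labels.astype(float), labels)
        assert ev.auc_roc == 1.0
        assert ev.auc_pr == 1.0

    def test_sign_flip_mirrors_auc(self):
        rng = np.random.default_rng(3)
        labels = (rng.random(100) < 0.5).astype(int)
        scores = rng.normal(size=100)
        a = roc_pr_curves(scores, labels).auc_roc
        b = roc_pr_curves(-scores, labels).auc_roc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        labels = (rng.random(80) < 0.5).astype(int)
        scores = rng.normal(size=80)
        a = roc_pr_curves(scores, labels).auc_roc
        b = roc_pr_curves(np.exp(3 * scores), labels).auc_roc
        assert a == pytest.approx(b, abs=1e-12)

    def test_roc_endpoints_anchored(self):
        rng = np.random.default_rng(5)
        labels = (rng.random(50) < 0.5).astype(int)
        ev = roc_pr_curves(rng.normal(size=50), labels)
        assert (ev.fpr[0], ev.tpr[0]) == (0.0, 0.0)
        assert (ev.fpr[-1], ev.tpr[-1]) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_curves(np.arange(5.0), np.ones(5, int))


class TestOperatingPoints:
    def test_perfect_classifier_all_criteria(self):
        labels = np.r_[np.zeros(20), np.ones(20)].astype(int)
        ev = roc_pr_curves(labels.astype(float), labels)
        for crit in ("youden", "specificity", "precision"):
            op = operating_points(ev, crit, target=0.95)
            assert (op.sensitivity, op.specificity, op.precision) == (1.0, 1.0, 1.0)

    def test_confusion_counts_recompute_to_curve_values(self):
        rng = np.random.default_rng(6)
        labels = (rng.random(60) < 0.5).astype(int)
        scores = rng.normal(labels.astype(float), 1.5)
        ev = roc_pr_curves(scores, labels)
        op = operating_points(ev, "youden")
        i = np.argmin(np.abs(ev.thresholds - op.threshold))
        tp, fp = ev.tps[i], ev.fps[i]
        fn = ev.n_pos - tp
        assert op.sensitivity == pytest.approx(tp / (tp + fn), abs=1e-12)

    def test_random_scores_at_high_specificity_have_low_sensitivity(self):
        rng = np.random.default_rng(7)
        labels = (rng.random(4000) < 0.5).astype(int)
        ev = roc_pr_curves(rng.normal(size=4000), labels)
        op = operating_points(ev, "specificity", target=0.95)
        assert op.sensitivity == pytest.approx(0.05, abs=0.03)

    def test_infeasible_precision_reported(self):
        labels = np.array([1, 0, 1, 0, 1, 0] * 5)
        scores = -labels.astype(float)  # anti-informative
        ev = roc_pr_curves(scores, labels)
        op = operating_points(ev, "precision", target=0.99)
        assert not op.feasible


class TestTuning:
    def test_separable_data_reaches_perfect_cv_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal(-4, 0.3, (30, 2)), rng.normal(4, 0.3, (30, 2))]
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        c, sigma = tune_hyperparams(X, y, seed=1)
        from embryomech.classify import _cv_scores, _stratified_folds
        folds = _stratified_folds(y, 10, np.random.default_rng(1))
        acc = np.mean((_cv_scores(X, y, c, sigma, folds) > 0) == y)
        assert acc == 1.0

    def test_deterministic_under_fixed_seed(self, human_cohort_df):
        X, y = feature_matrix(human_cohort_df)
        assert tune_hyperparams(X, y, seed=3) == tune_hyperparams(X, y, seed=3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparams(np.random.rand(20, 2), np.ones(20, int))


class TestMcCrossValidate:
    def test_separated_classes_give_unit_aucs(self):
        rng = np.random.default_rng(1)
        X = np.r_[rng.normal(-5, 0.2, (30, 2)), rng.normal(5, 0.2, (30, 2))]
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        mc = mc_cross_validate(X, y, c=1.0, sigma=1.0, n_mc=5, seed=0)
        assert mc.mean_auc_roc == 1.0
        assert mc.mean_auc_pr == pytest.approx(1.0, abs=1e-12)

    def test_determinism(self, human_cohort_df):
        X, y = feature_matrix(human_cohort_df)
        a = mc_cross_validate(X, y, 2.0, 1.0, n_mc=5, seed=9)
        b = mc_cross_validate(X, y, 2.0, 1.0, n_mc=5, seed=9)
        assert a.per_rep.equals(b.per_rep)

    def test_no_optimistic_bias_on_pure_noise(self):
        # out-of-fold discipline: many noise features must not inflate AUC
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 15))
        y = (rng.random(80) < 0.5).astype(int)
        mc = mc_cross_validate(X, y, c=8.0, sigma=1.0, n_mc=20, seed=3)
        assert 0.38 <= mc.mean_auc_roc <= 0.62

    def test_noisier_labels_lower_auc(self):
        aucs = []
        for noise in (0.0, 0.15, 0.35):
            df = cohort_to_frame(sample_cohort(
                CohortSpec(seed=21, label_noise=noise,
                           n_viable=60, n_nonviable=60)))
            X, y = feature_matrix(df, ("k1", "log_eta1", "k0"))
            mc = mc_cross_validate(X, y, c=2.0, sigma=1.0, n_mc=10, seed=4)
            aucs.append(mc.mean_auc_roc)
        assert aucs[0] > aucs[1] > aucs[2]


class TestForwardSelection:
    def test_informative_feature_selected_first(self):
        rng = np.random.default_rng(5)
        n = 100
        y = (rng.random(n) < 0.5).astype(int)
        X = pd.DataFrame({
            "signal": y + rng.normal(0, 0.4, n),
            "noise_a": rng.normal(size=n),
            "noise_b": rng.normal(size=n),
            "noise_c": rng.normal(size=n),
        })
        path = forward_feature_select(X, y, seed=0, n_rep=2)
        assert path.feature.iloc[0] == "signal"

    def test_noise_feature_adds_no_auc_beyond_plateau(self, human_cohort_df):
        X, y = feature_matrix(human_cohort_df)
        path = forward_feature_select(X, y, seed=1)
        assert path.auc_roc.iloc[3] <= path.auc_roc.iloc[2] + 0.02

    def test_deterministic_path(self, human_cohort_df):
        X, y = feature_matrix(human_cohort_df)
        a = forward_feature_select(X, y, seed=2, n_rep=2)
        b = forward_feature_select(X, y, seed=2, n_rep=2)
        assert a.equals(b)

    def test_needs_two_features(self):
        X = pd.DataFrame({"only": np.arange(20.0)})
        y = (np.arange(20) % 2)
        with pytest.raises(ValueError):
            forward_feature_select(X, y)


class TestCombineFeatures:
    def test_disjoint_ids_error_lists_offenders(self, human_cohort_df):
        X, y = feature_matrix(human_cohort_df, ("k1", "log_eta1"))
        cc, _ = feature_matrix(human_cohort_df, ("c1", "c2"))
        cc_bad = cc.rename(index={cc.index[0]: "stranger"})
        with pytest.raises(ValueError, match="stranger"):
            combine_features(X, cc_bad)

    def test_combined_modalities_do_not_hurt(self, human_cohort_df):
        mech, y = feature_matrix(human_cohort_df, ("k1", "log_eta1"))
        cc, _ = feature_matrix(human_cohort_df, ("c1", "c2"))
        both = combine_features(mech, cc)
        kw = dict(c=2.0, sigma=2.0, n_mc=10, seed=5)
        auc_m = mc_cross_validate(mech, y, **kw).mean_auc_roc
        auc_c = mc_cross_validate(cc, y, **kw).mean_auc_roc
        auc_b = mc_cross_validate(both, y, **kw).mean_auc_roc
        assert auc_b >= max(auc_m, auc_c) - 0.05

    def test_column_order_invariance(self, human_cohort_df):
        X, y = feature_matrix(human_cohort_df)
        shuffled = X[list(X.columns[::-1])]
        a = mc_cross_validate(X, y, 2.0, 1.0, n_mc=3, seed=6).per_rep
        b = mc_cross_validate(shuffled, y, 2.0, 1.0, n_mc=3, seed=6).per_rep
        assert a.equals(b)


class TestTrainedClassifier:
    def test_train_predict_round_trip(self, human_cohort_df):
        X, y = feature_matrix(human_cohort_df, ("k1", "log_eta1", "k0"))
        clf = TrainedClassifier.train(X, y, c=2.0, sigma=1.0)
        pred = clf.predict(X)
        assert pred.dtype == bool
        assert np.mean(pred == y.astype(bool)) > 0.8  # resubstitution sanity

    def test_standardization_state_stored(self, human_cohort_df):
        X, y = feature_matrix(human_cohort_df, ("k1", "k0"))
        clf = TrainedClassifier.train(X, y)
        np.testing.assert_allclose(clf.center, X.to_numpy().mean(axis=0))
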