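"""PLS, component selection, SVM grid search and report identities."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import serscreen as ss
from serscreen.chemometrics import (
    ChemometricsConfig,
    ClassificationReport,
    LabeledSpectraMatrix,
    SVMHyperParams,
    classify_and_report,
    compute_msep_curve,
    fit_pls,
    grid_search_svm,
    run_pls_svm,
    select_components,
)
from serscreen.synthetic import generate_latent_cohort


def _random_labeled(seed, n=20, p=50, classes=("A", "B", "C")):
    rng = np.random.default_rng(seed)
    return LabeledSpectraMatrix(
        X=rng.normal(size=(n, p)), y=tuple(rng.choice(classes, size=n))
    )


class TestFitPLS:
    def test_rank_one_separable_data_needs_one_component(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=30)
        t = np.concatenate([rng.normal(-5, 0.1, 10), rng.normal(5, 0.1, 10)])
        X = np.outer(t, direction)
        data = LabeledSpectraMatrix(X=X, y=tuple("A" * 10 + "B" * 10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_pls(data, 1)
        assert fit.cumulative_proportion[0] > 0.99

    def test_scores_mutually_orthogonal(self):
        fit = fit_pls(_random_labeled(1), 5)
        gram = fit.scores.T @ fit.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_cumulative_proportion_monotone_in_unit_interval(self):
        fit = fit_pls(_random_labeled(2), 6)
        cp = fit.cumulative_proportion
        assert np.all(np.diff(cp) >= -1e-12)
        assert np.all((cp >= 0) & (cp <= 1))

    def test_matches_reference_nipals_to_1e6(self):
        """Independent oracle: sklearn's NIPALS PLS2 on a 20×50 seeded matrix
        must agree with our implementation up to per-component sign."""
        from sklearn.cross_decomposition import PLSRegression

        data = _random_labeled(42)
        fit = fit_pls(data, 5)
        Y = np.zeros((20, len(fit.classes)))
        for i, yi in enumerate(data.y):
            Y[i, fit.classes.index(yi)] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = PLSRegression(n_components=5, scale=False, tol=1e-14,
                                max_iter=50000).fit(data.X, Y)
        for k in range(5):
            sign = np.sign(fit.scores[:, k] @ ref.x_scores_[:, k])
            np.testing.assert_allclose(
                fit.scores[:, k], sign * ref.x_scores_[:, k],
                atol=1e-6 * np.max(np.abs(fit.scores[:, k])),
            )
            np.testing.assert_allclose(
                fit.loadings[:, k], sign * ref.x_loadings_[:, k],
                atol=1e-6 * np.max(np.abs(fit.loadings[:, k])),
            )

    def test_single_class_rejected(self):
        data = LabeledSpectraMatrix(X=np.eye(4), y=("A",) * 4)
        with pytest.raises(ss.ChemometricsError, match="class"):
            fit_pls(data, 2)

    def test_transform_reproduces_training_scores(self):
        data = _random_labeled(3)
        fit = fit_pls(data, 4)
        np.testing.assert_allclose(fit.transform(data.X, 4), fit.scores,
                                   atol=1e-8)


class TestMSEPCurve:
    def test_rank_one_data_drops_msep_by_90_percent(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=30)
        t = np.concatenate([rng.normal(-5, 0.05, 12), rng.normal(5, 0.05, 12)])
        X = np.outer(t, direction) + rng.normal(0, 1e-4, (24, 30))
        data = LabeledSpectraMatrix(X=X, y=tuple("A" * 12 + "B" * 12))
        sel = compute_msep_curve(data, 3, folds=4, seed=0)
        assert sel.msep_curve[1] < 0.1 * sel.msep_curve[0]

    def test_seeded_determinism(self):
        data = _random_labeled(5)
        a = compute_msep_curve(data, 4, folds=5, seed=9)
        b = compute_msep_curve(data, 4, folds=5, seed=9)
        np.testing.assert_array_equal(a.msep_curve, b.msep_curve)

    def test_elbow_at_three_planted_factors(self):
        X, y = generate_latent_cohort(0)
        sel = compute_msep_curve(LabeledSpectraMatrix(X=X, y=y), 8, folds=10, seed=0)
        assert select_components(sel, 0.05) == 3


class TestSelectComponents:
    def test_hand_computed_curve_cuts_at_three(self):
        # improvements: 60%, 50%, 25%, then (0.15-0.149)/0.15 = 0.67% < 5%
        assert select_components([1.00, 0.40, 0.20, 0.15, 0.149], 0.05) == 3

    def test_flat_curve_floors_at_one(self):
        assert select_components([1.0, 1.0, 1.0, 1.0], 0.05) == 1

    def test_always_improving_curve_returns_maximum(self):
        assert select_components([1.0, 0.5, 0.25, 0.125], 0.05) == 3

    def test_ratio_form_agrees_on_reference_curve(self):
        curve = [1.00, 0.40, 0.20, 0.15, 0.149]
        assert select_components(curve, 0.05, form="ratio") == 3

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_in_threshold(self, seed):
        """A stricter improvement requirement can never keep more components."""
        rng = np.random.default_rng(seed)
        curve = np.abs(rng.normal(1, 0.5, 6)).cumsum()[::-1] + 0.01
        loose = select_components(curve, 0.02)
        strict = select_components(curve, 0.20)
        assert strict <= loose


class TestGridSearchSVM:
    def test_separated_clouds_reach_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-20, 0.5, (15, 2)), rng.normal(20, 0.5, (15, 2))])
        y = tuple("A" * 15 + "B" * 15)
        res = grid_search_svm(X, y, folds=5, seed=0)
        assert res.best_accuracy == 1.0
        assert (res.grid["accuracy"] == 1.0).mean() > 0.3

    def test_xor_needs_nonlinear_kernel(self):
        """RBF-SVM solves the XOR layout that no single linear threshold can."""
        rng = np.random.default_rng(1)
        centers = [(-3, -3), (3, 3), (-3, 3), (3, -3)]
        X = np.vstack([c + rng.normal(0, 0.4, (10, 2)) for c in centers])
        y = tuple("A" * 20 + "B" * 20)
        res = grid_search_svm(X, y, folds=5, seed=1)
        assert res.best_accuracy > 0.9
        # exhaustive single-feature threshold baseline
        best_linear = 0.0
        y_arr = np.array(y)
        for j in (0, 1):
            for thr in np.unique(X[:, j]):
                for sign in (1, -1):
                    pred = np.where(sign * (X[:, j] - thr) > 0, "A", "B")
                    best_linear = max(best_linear, np.mean(pred == y_arr))
        assert best_linear <= 0.6

    def test_seeded_determinism_of_surface(self):
        data = _random_labeled(7, n=24, p=3, classes=("A", "B"))
        a = grid_search_svm(data.X, data.y, c_grid=(0.1, 1), sigma_grid=(0.5, 1), folds=4, seed=2)
        b = grid_search_svm(data.X, data.y, c_grid=(0.1, 1), sigma_grid=(0.5, 1), folds=4, seed=2)
        np.testing.assert_array_equal(a.grid["accuracy"], b.grid["accuracy"])
        assert a.best_params == b.best_params

    def test_every_sample_predicted_once_with_stratified_folds(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        y = tuple(np.repeat(["A", "B", "C"], 10))
        res = grid_search_svm(X, y, c_grid=(1.0,), sigma_grid=(1.0,), folds=5, seed=0)
        assert len(res.predictions) == 30
        counts = np.bincount(res.fold_assignments)
        assert np.all(counts == 6)  # 3 classes × 2 per fold


class TestClassificationReport:
    def test_confusion_matrix_identities(self):
        M = [[27, 1, 2], [1, 28, 1], [2, 1, 27]]
        rep = ClassificationReport.from_confusion(M, ("Sham", "OVX", "ICA"),
                                                  positive_class="OVX")
        assert rep.accuracy == pytest.approx(82 / 90)
        assert rep.sensitivity["OVX"] == pytest.approx(28 / 30)
        assert rep.specificity["OVX"] == pytest.approx(58 / 60)
        np.testing.assert_array_equal(np.asarray(M).sum(axis=1), [30, 30, 30])

    def test_all_wrong_predictions(self):
        M = [[0, 5], [5, 0]]
        rep = ClassificationReport.from_confusion(M, ("A", "B"))
        assert rep.accuracy == 0.0
        assert rep.sensitivity["A"] == 0.0 and rep.sensitivity["B"] == 0.0

    def test_perfect_ranking_gives_auc_one(self):
        from sklearn.metrics import auc, roc_curve

        y = np.array(["neg"] * 10 + ["pos"] * 10)
        scores = np.concatenate([np.arange(10), np.arange(100, 110)])
        fpr, tpr, _ = roc_curve(y == "pos", scores)
        assert auc(fpr, tpr) == 1.0

    def test_auc_flips_under_label_swap_for_fixed_scores(self, rng):
        """Keeping the decision values fixed and relabelling the positives
        mirrors the ROC: AUC becomes 1 − AUC."""
        from serscreen.chemometrics import _roc

        y = np.array(["neg"] * 12 + ["pos"] * 12)
        scores = rng.normal(size=24)
        _, auc_pos = _roc(y, scores, "pos")
        _, auc_neg = _roc(y, scores, "neg")
        assert auc_neg == pytest.approx(1.0 - auc_pos, abs=1e-12)

    def test_unknown_positive_class_rejected(self, rng):
        X = rng.normal(size=(12, 2))
        y = tuple("AB" * 6)
        with pytest.raises(ss.ChemometricsError, match="positive_class"):
            classify_and_report(X, y, SVMHyperParams(), folds=3, seed=0,
                                positive_class="Z")


class TestRunPLSSVM:
    def test_no_signal_null_is_near_chance(self):
        """With group effects disabled the cohort carries no class signal, so
        end-to-end CV accuracy must hover at 1/3."""
        effects = tuple(ss.GroupEffectProfile(g, {}) for g in ("Sham", "OVX", "ICA"))
        accs = []
        for seed in range(3):
            cfg = ss.default_config(effects=effects, n_samples_per_group=10,
                                    n_replicates=1, seed=seed)
            samples = ss.preprocess_records(ss.generate_cohort(cfg))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_pls_svm(
                    LabeledSpectraMatrix.from_samples(samples),
                    ChemometricsConfig(seed=seed, c_grid=(1.0,), sigma_grid=(1.0,),
                                       binary_tasks=False, folds=5),
                )
            accs.append(res.three_class.report.accuracy)
        assert 0.1 < np.mean(accs) < 0.6

    def test_determinism_of_full_run(self, small_samples):
        data = LabeledSpectraMatrix.from_samples(small_samples)
        cfg = ChemometricsConfig(seed=5, folds=4, c_grid=(1.0, 10.0),
                                 sigma_grid=(0.5, 1.0), n_components_max=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_pls_svm(data, cfg)
            b = run_pls_svm(data, cfg)
        assert a.three_class.cv.best_params == b.three_class.cv.best_params
        np.testing.assert_array_equal(a.three_class.report.confusion,
                                      b.three_class.report.confusion)
        assert a.three_class.report.auc == b.three_class.report.auc

    def test_binary_tasks_present_with_expected_positive_classes(self, small_samples):
        data = LabeledSpectraMatrix.from_samples(small_samples)
        cfg = ChemometricsConfig(seed=0, folds=4, c_grid=(1.0,), sigma_grid=(1.0,),
                                 n_components_max=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_pls_svm(data, cfg)
        assert set(res.tasks) == {"all", "ICA_vs_OVX", "ICA_vs_Sham", "OVX_vs_Sham"}
        assert res.tasks["all"].report.positive_class == "OVX"
        assert res.tasks["ICA_vs_Sham"].report.positive_class == "ICA"

    def test_accuracy_degrades_with_noise(self):
        """Synthetic power curve: more measurement noise, less discrimination."""
        accs = []
        for noise in (1.0, 30.0):
            cfg = ss.default_config(n_samples_per_group=8, n_replicates=2,
                                    noise_sd=noise, seed=2)
            samples = ss.preprocess_records(ss.generate_cohort(cfg))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_pls_svm(
                    LabeledSpectraMatrix.from_samples(samples),
                    ChemometricsConfig(seed=2, folds=4, c_grid=(1.0,),
                                       sigma_grid=(1.0,), binary_tasks=False),
                )
            accs.append(res.three_class.report.accuracy)
        assert accs[1] <= accs[0]
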