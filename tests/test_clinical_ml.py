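"""Stratified Monte-Carlo splits, SVM diagnosis and surgery-simulation regression."""

import numpy as np
import pandas as pd
import pytest

from facemorph.clinical_ml import (
    CohortTable,
    SplitSpec,
    classify_diagnosis,
    evaluate_regression,
    fit_surgery_regressor,
    make_splits,
    simulate_postop,
    train_counts,
)
from facemorph.mesh_core import FlatShape
from facemorph.morphable_model import fit_pca


def _labels(n_pat, n_vol):
    return np.array([1] * n_pat + [0] * n_vol)


def _cohort(n_pat, n_vol):
    rows = [{"scan_id": f"p{i}", "subject_id": f"P{i}", "group": "preop"}
            for i in range(n_pat)]
    rows += [{"scan_id": f"v{i}", "subject_id": f"V{i}", "group": "volunteer"}
             for i in range(n_vol)]
    return CohortTable(pd.DataFrame(rows)), [r["scan_id"] for r in rows]


class TestCohortTable:
    def test_duplicate_scan_id_rejected(self):
        df = pd.DataFrame({"scan_id": ["a", "a"], "subject_id": ["s", "s"],
                           "group": ["preop", "postop"]})
        with pytest.raises(ValueError, match="duplicate"):
            CohortTable(df)

    def test_orphan_postop_rejected(self):
        df = pd.DataFrame({
            "scan_id": ["a", "b"], "subject_id": ["s1", "s2"],
            "group": ["preop", "postop"], "pair_id": ["x", "y"],
        })
        with pytest.raises(ValueError, match="orphan|matching"):
            CohortTable(df)

    def test_pairs_join(self):
        df = pd.DataFrame({
            "scan_id": ["a", "b", "c"], "subject_id": ["s", "s", "t"],
            "group": ["preop", "postop", "volunteer"], "pair_id": ["x", "x", None],
        })
        pairs = CohortTable(df).pairs()
        assert len(pairs) == 1
        assert pairs.iloc[0].preop_scan == "a" and pairs.iloc[0].postop_scan == "b"


class TestSplits:
    def test_published_split_arithmetic(self):
        """140 patients + 280 volunteers at 80-20 give 112/224 train, 28/56 test."""
        counts = train_counts({"patient": 140, "volunteer": 280}, 0.8)
        assert counts == {"patient": 112, "volunteer": 224}
        y = _labels(140, 280)
        train, test = next(make_splits(y, SplitSpec(0.8, 1, seed=0)))
        assert (y[train] == 1).sum() == 112 and (y[train] == 0).sum() == 224
        assert (y[test] == 1).sum() == 28 and (y[test] == 0).sum() == 56

    @pytest.mark.parametrize("fraction,n_pat,n_vol,expect_pat,expect_vol", [
        (0.8, 119, 300, 95, 240),
        (0.6, 140, 280, 84, 168),
        (0.5, 140, 280, 70, 140),
    ])
    def test_split_arithmetic_other_fractions(self, fraction, n_pat, n_vol,
                                              expect_pat, expect_vol):
        counts = train_counts({"p": n_pat, "v": n_vol}, fraction)
        assert counts == {"p": expect_pat, "v": expect_vol}

    def test_full_train_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0, n_iterations=1)

    def test_seed_determinism(self):
        y = _labels(20, 40)
        spec = SplitSpec(0.8, 25, seed=9)
        runs = [[(tr.tolist(), te.tolist()) for tr, te in make_splits(y, spec)]
                for _ in range(2)]
        assert runs[0] == runs[1]

    def test_no_leakage_and_marginals_every_iteration(self):
        y = _labels(15, 30)
        for train, test in make_splits(y, SplitSpec(0.8, 50, seed=2)):
            assert len(np.intersect1d(train, test)) == 0
            assert len(train) + len(test) == len(y)
            assert (y[test] == 1).sum() == 3 and (y[test] == 0).sum() == 6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            next(make_splits(np.zeros(10, dtype=int), SplitSpec(0.8, 1)))


@pytest.fixture(scope="module")
def separable_features():
    """Patient/volunteer coefficients separated far beyond their spread."""
    rng = np.random.default_rng(12)
    n_pat, n_vol, d = 20, 40, 6
    vol = rng.normal(size=(n_vol, d))
    pat = rng.normal(size=(n_pat, d))
    pat[:, 1] += 10.0  # one coefficient carries the jaw effect
    cohort, ids = _cohort(n_pat, n_vol)
    X = np.vstack([pat, vol])
    return cohort, ids, X


class TestClassification:
    def test_separable_cohort_high_accuracy(self, separable_features):
        cohort, ids, X = separable_features
        rep = classify_diagnosis(cohort, X, ids, SplitSpec(0.8, 100, seed=1))
        assert rep.accuracy > 0.95
        assert rep.n_iterations == 100

    def test_confusion_marginals_match_test_counts(self, separable_features):
        cohort, ids, X = separable_features
        rep = classify_diagnosis(cohort, X, ids, SplitSpec(0.8, 50, seed=3))
        # test partition: 4 patients, 8 volunteers per iteration
        assert rep.tp + rep.fn == pytest.approx(4.0)
        assert rep.tn + rep.fp == pytest.approx(8.0)

    def test_metrics_recomputable_from_confusion_matrix(self, separable_features):
        cohort, ids, X = separable_features
        rep = classify_diagnosis(cohort, X, ids, SplitSpec(0.8, 20, seed=5))
        assert rep.sensitivity == pytest.approx(rep.tp / (rep.tp + rep.fn))
        assert rep.ppv == pytest.approx(rep.tp / (rep.tp + rep.fp))
        assert 0.0 <= rep.npv <= 1.0 and 0.0 <= rep.specificity <= 1.0

    def test_permuted_labels_fall_to_chance(self, separable_features):
        cohort, ids, X = separable_features
        rng = np.random.default_rng(8)
        X_perm = X[rng.permutation(len(X))]  # break the feature-label link
        rep = classify_diagnosis(cohort, X_perm, ids, SplitSpec(0.8, 100, seed=2))
        assert 0.4 <= rep.accuracy <= 0.75  # chance for a 1:2 class ratio is ~2/3 at worst

    def test_misclassification_tallies_bounded(self, separable_features):
        cohort, ids, X = separable_features
        rep = classify_diagnosis(cohort, X, ids, SplitSpec(0.8, 30, seed=4))
        mis = rep.misclassification
        assert (mis.times_misclassified <= mis.times_tested).all()
        assert mis.times_tested.sum() == 30 * 12  # 12 test scans per iteration


class TestSurgeryRegression:
    def test_noiseless_linear_map_recovered_by_lr(self, rng):
        k, n = 5, 40
        A = rng.normal(size=(k, k))
        pre = rng.normal(size=(n, k))
        post = pre @ A.T
        reg = fit_surgery_regressor("LR", pre, post)
        assert np.allclose(reg.coef, A, atol=1e-8)
        assert np.allclose(reg.predict(pre[0]), post[0], atol=1e-8)

    def test_identity_surgery_rr_error_vanishes_with_alpha(self, rng):
        pre = rng.normal(size=(30, 4)) * 5
        errs = []
        for alpha in (10.0, 1.0, 1e-4):
            reg = fit_surgery_regressor("RR", pre, pre, hyper={"alpha": alpha})
            errs.append(np.abs(reg.predict(pre) - pre).mean())
        assert errs[0] > errs[1] > errs[2]
        assert errs[-1] < 1e-3

    def test_lars_budget_one_predictor_per_output(self, rng):
        pre = rng.normal(size=(50, 6))
        post = pre * 0.3  # diagonal map: best single predictor of output j is input j
        reg = fit_surgery_regressor("LARS", pre, post)
        assert np.all((np.abs(reg.coef) > 1e-12).sum(axis=1) <= 1)

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_surgery_regressor("LR", rng.normal(size=(1, 3)), rng.normal(size=(1, 3)))

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown method"):
            fit_surgery_regressor("GBM", rng.normal(size=(5, 2)), rng.normal(size=(5, 2)))


@pytest.fixture(scope="module")
def paired_cohort_model(tiny_cohort):
    """Global model + paired preop/postop flat shapes from the synthetic cohort."""
    corr = tiny_cohort.ground_truth_corresponded()
    model = fit_pca(corr, id="global")
    pairs = tiny_cohort.cohort.pairs()
    ids = corr.scan_ids
    X = corr.data_matrix()
    pre = np.stack([X[ids.index(s)] for s in pairs.preop_scan])
    post = np.stack([X[ids.index(s)] for s in pairs.postop_scan])
    return model, pre, post, pairs.pair_id.tolist()


class TestSimulatePostop:
    def test_identity_regressor_returns_projection(self, paired_cohort_model):
        model, pre, _, _ = paired_cohort_model
        k = model.n_components
        from facemorph.clinical_ml import SurgeryRegressor

        ident = SurgeryRegressor("LR", k, np.eye(k), np.zeros(k))
        out = simulate_postop(model, ident, FlatShape(pre[0]))
        _, proj = model.project(FlatShape(pre[0]))
        assert np.allclose(out.vertices.reshape(-1), proj.x, atol=1e-9)

    def test_zero_regressor_returns_mean_face(self, paired_cohort_model):
        model, pre, _, _ = paired_cohort_model
        k = model.n_components
        from facemorph.clinical_ml import SurgeryRegressor

        zero = SurgeryRegressor("LR", k, np.zeros((k, k)), np.zeros(k))
        out = simulate_postop(model, zero, FlatShape(pre[0]))
        assert np.allclose(out.vertices.reshape(-1), model.mean.x)

    def test_learnt_operator_beats_noise_floor(self, tiny_cohort, paired_cohort_model):
        """Prediction error stays within the generator's noise scale + margin."""
        model, pre, post, pair_ids = paired_cohort_model
        k = model.n_components
        alphas_pre = np.stack([model.project(FlatShape(x))[0].alpha for x in pre])
        alphas_post = np.stack([model.project(FlatShape(x))[0].alpha for x in post])
        reg = fit_surgery_regressor("RR", alphas_pre, alphas_post)
        pred = simulate_postop(model, reg, FlatShape(pre[0]))
        truth = post[0].reshape(-1, 3)
        aed = np.linalg.norm(pred.vertices - truth, axis=1).mean()
        # in-sample fit on a clean linear operator: noise (0.2 mm here) + 0.2 mm slack
        assert aed < 0.2 * np.sqrt(2) + 0.2


class TestEvaluateRegression:
    def test_report_bookkeeping(self, paired_cohort_model):
        model, pre, post, pair_ids = paired_cohort_model
        report = evaluate_regression(model, pre, post, pair_ids,
                                     methods=("LR", "RR"), k_grid=(2, 4))
        assert len(report.folds) == 2 * 2 * len(pair_ids)
        assert set(report.folds.method) == {"LR", "RR"}
        assert (report.folds.aed_truth_mm >= 0).all()

    def test_noiseless_identity_surgery_near_zero(self, clean_cohort):
        corr = clean_cohort.ground_truth_corresponded(noisy=False)
        model = fit_pca(corr, id="global")
        pairs = clean_cohort.cohort.pairs()
        ids, X = corr.scan_ids, corr.data_matrix()
        pre = np.stack([X[ids.index(s)] for s in pairs.preop_scan])
        # identity surgery at full rank: postop equals preop exactly
        report = evaluate_regression(model, pre, pre, pairs.pair_id.tolist(),
                                     methods=("LR", "RR", "LASSO"),
                                     k_grid=(model.n_components,))
        summary = report.summary()
        assert summary[summary.method == "LR"].mean_mm.iloc[0] < 1e-6
        assert summary[summary.method == "RR"].mean_mm.iloc[0] < 0.2

    def test_regularisation_beats_lr_when_k_approaches_n(self, rng):
        """Overfitting ordering: with k close to the pair count, LR degrades."""
        n3, k, n_pairs = 120, 20, 24
        U, _ = np.linalg.qr(rng.normal(size=(n3, k)))
        mean = rng.normal(size=n3)
        A = np.eye(k) * 0.5
        a_pre = rng.normal(size=(n_pairs, k)) * np.linspace(6, 1, k)
        a_post = a_pre @ A.T
        pre = mean + a_pre @ U.T + rng.normal(scale=0.3, size=(n_pairs, n3))
        post = mean + a_post @ U.T + rng.normal(scale=0.3, size=(n_pairs, n3))
        model = fit_pca(np.vstack([pre, post]), template_faces=np.array([[0, 1, 2]]))
        report = evaluate_regression(model, pre, post, [f"p{i}" for i in range(n_pairs)],
                                     methods=("LR", "RR", "LARS", "LASSO"), k_grid=(k,))
        s = report.summary().set_index("method")["mean_mm"]
        assert s["RR"] < s["LR"]
        assert s["LARS"] < s["LR"]
        assert s["LASSO"] < s["LR"]

    def test_predictions_are_patient_specific(self, paired_cohort_model):
        """Prediction-vs-truth AED beats prediction-vs-mean-face baselines."""
        model, pre, post, pair_ids = paired_cohort_model
        # keep the map identifiable: fewer components than training pairs
        k = min(model.n_components, len(pair_ids) - 1)
        report = evaluate_regression(model, pre, post, pair_ids,
                                     methods=("RR",), k_grid=(k,))
        s = report.summary().iloc[0]
        assert s.mean_mm < s.mean_vs_global_mean_mm
        assert s.mean_mm < s.mean_vs_postop_mean_mm

    def test_best_and_worst_cases_reported(self, paired_cohort_model):
        model, pre, post, pair_ids = paired_cohort_model
        report = evaluate_regression(model, pre, post, pair_ids,
                                     methods=("RR",), k_grid=(3,))
        best, worst = report.best_and_worst("RR", 3)
        assert best.aed_truth_mm <= worst.aed_truth_mm

    def test_too_few_pairs_rejected(self, paired_cohort_model, rng):
        model, pre, post, _ = paired_cohort_model
        with pytest.raises(ValueError):
            evaluate_regression(model, pre[:2], post[:2], ["a", "b"])
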