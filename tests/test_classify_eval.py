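import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from mammotex.classify_eval import (
    CLASSIFIERS,
    ConfusionTable,
    evaluate,
    loocv_scores,
    metrics_from_confusion,
    predict_scores,
    run_experiment,
    split_cases,
    train_classifier,
)

from _oracles import auc_pairs_brute


def _separable(rng, n_per_class=20, spread=0.3):
    X = np.r_[rng.normal(0, spread, (n_per_class, 2)), rng.normal(3, spread, (n_per_class, 2))]
    y = np.r_[np.zeros(n_per_class), np.ones(n_per_class)].astype(int)
    return X, y


class TestSplit:
    def test_stratified_70_30(self, rng):
        ids = [f"c{i}" for i in range(100)]
        labels = np.r_[np.ones(60), np.zeros(40)].astype(int)
        train, test = split_cases(ids, labels, 0.70, seed=1)
        assert len(train) == 70 and len(test) == 30
        lab = dict(zip(ids, labels))
        assert abs(sum(lab[i] for i in train) - 42) <= 1

    def test_same_seed_same_split(self):
        ids = [f"c{i}" for i in range(40)]
        labels = [i % 2 for i in range(40)]
        assert split_cases(ids, labels, seed=3) == split_cases(ids, labels, seed=3)

    def test_paired_views_never_straddle(self):
        # subjects s0..s19, each with left+right views
        ids = [f"s{i}{side}" for i in range(20) for side in ("l", "r")]
        labels = [i % 2 for i in range(20) for _ in ("l", "r")]
        train, test = split_cases(ids, labels, seed=7)
        train_subj = {i[:-1] for i in train}
        test_subj = {i[:-1] for i in test}
        assert not (train_subj & test_subj)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            split_cases(["a", "b", "c"], [1, 0, 0])


class TestTrainEvaluate:
    @pytest.mark.parametrize("name", CLASSIFIERS)
    def test_separable_training_accuracy_one(self, name, rng):
        X, y = _separable(rng)
        model = train_classifier(name, X, y, seed=0)
        assert (model.predict(X) == y).all()

    @pytest.mark.parametrize("name", CLASSIFIERS)
    def test_deterministic_under_seed(self, name, rng):
        X, y = _separable(rng, spread=1.5)
        Xt = rng.normal(1.5, 1.5, (30, 2))
        p1 = train_classifier(name, X, y, seed=4).predict(Xt)
        p2 = train_classifier(name, X, y, seed=4).predict(Xt)
        np.testing.assert_array_equal(p1, p2)

    def test_unknown_name_rejected(self, rng):
        X, y = _separable(rng)
        with pytest.raises(ValueError, match="unknown classifier"):
            train_classifier("lda", X, y)

    def test_single_class_training_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="single class"):
            train_classifier("svm", X, np.ones(10))

    def test_perfect_predictions_all_metrics_one(self, rng):
        X, y = _separable(rng)
        model = train_classifier("svm", X, y, seed=0)
        ct, ms = evaluate(model, X, y)
        assert ct.FP == ct.FN == 0
        for v in ms.as_dict().values():
            assert v == pytest.approx(1.0)

    def test_all_positive_predictor(self):
        class AllPos:
            def predict(self, X):
                return np.ones(len(X), dtype=int)

            def decision_function(self, X):
                return np.zeros(len(X))

        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        ct, ms = evaluate(AllPos(), np.zeros((20, 2)), y)
        assert ms.sensitivity == 1.0 and ms.specificity == 0.0
        assert ms.balanced_accuracy == 0.5
        assert ms.NPV is None  # zero denominator reported as absent

    def test_metrics_consistent_with_confusion(self, rng):
        X, y = _separable(rng, spread=2.5)
        model = train_classifier("dt", X, y, seed=0)
        ct, ms = evaluate(model, X, y)
        re = metrics_from_confusion(ct, ms.AUC)
        for k, v in ms.as_dict().items():
            if v is None:
                assert getattr(re, k) is None
            else:
                assert abs(v - getattr(re, k)) < 1e-12

    def test_auc_matches_pair_counting_and_sklearn(self, rng):
        X, y = _separable(rng, n_per_class=12, spread=2.0)
        model = train_classifier("nb", X, y, seed=0)
        scores = predict_scores(model, X)
        _, ms = evaluate(model, X, y)
        assert ms.AUC == pytest.approx(auc_pairs_brute(scores, y), abs=1e-12)
        assert ms.AUC == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_label_permutation_auc_near_half(self, rng):
        X, y = _separable(rng, n_per_class=30, spread=0.5)
        aucs = []
        for s in range(10):
            perm = np.random.default_rng(s).permutation(y)
            if len(np.unique(perm)) < 2:
                continue
            model = train_classifier("svm", X, perm, seed=0)
            _, ms = evaluate(model, X, y)
            aucs.append(ms.AUC)
        assert abs(np.mean(aucs) - 0.5) < 0.15


class TestLOOCV:
    def test_three_cases_three_scores(self):
        X = np.array([[0.0], [1.0], [10.0]])
        y = np.array([0, 0, 1])
        with pytest.warns(UserWarning, match="single-class"):
            scores = loocv_scores("dt", X, y)
        assert len(scores) == 3

    def test_separable_loocv_accuracy_one_knn(self, rng):
        X, y = _separable(rng, n_per_class=10)
        scores = loocv_scores("knn", X, y)
        assert (((scores > 0.5).astype(int)) == y).all()

    def test_loocv_auc_close_to_heldout(self, easy_features_clahe_usm):
        from mammotex.classify_eval import _task_labels
        from mammotex.select import rank_auc
        from mammotex.texture import FEATURE_NAMES

        sub, y = _task_labels(easy_features_clahe_usm, "normal_abnormal")
        X = sub[FEATURE_NAMES].to_numpy()
        train, test = split_cases(sub["id"], y, seed=0)
        tr = sub["id"].isin(train).to_numpy()
        cv = rank_auc(loocv_scores("nb", X[tr], y[tr], seed=0), y[tr])
        model = train_classifier("nb", X[tr], y[tr], seed=0)
        _, ms = evaluate(model, X[~tr], y[~tr])
        assert abs(cv - ms.AUC) <= 0.1


class TestRunExperiment:
    def _tables(self, rng, combos=("CLAHE", "MF_CLAHE"), n=40):
        from mammotex.texture import FEATURE_NAMES

        tables = {}
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        sev = np.where(np.arange(n) % 2 == 0, "benign", "malign")
        for c in combos:
            X = rng.standard_normal((n, 33)) + 2.0 * y[:, None]
            t = pd.DataFrame(X, columns=FEATURE_NAMES)
            t.insert(0, "severity", np.where(y == 1, sev, ""))
            t.insert(0, "tissue_class", np.where(y == 1, "abnormal", "normal"))
            t.insert(0, "id", [f"c{i}" for i in range(n)])
            tables[c] = t
        return tables

    def test_full_factorial_row_count(self, rng):
        report, plot = run_experiment(self._tables(rng), "normal_abnormal", seed=0)
        assert len(report) == 2 * 6
        assert set(report["classifier"]) == set(CLASSIFIERS)
        assert plot.shape == (2, 6)

    def test_benign_malign_excludes_normals(self, rng):
        tables = self._tables(rng)
        report, _ = run_experiment(tables, "benign_malign", seed=0)
        n_abnormal = (tables["CLAHE"]["tissue_class"] == "abnormal").sum()
        assert (report["n_train"] + report["n_test"] == n_abnormal).all()

    def test_failed_cell_marked_and_run_continues(self, rng):
        tables = self._tables(rng, combos=("CLAHE",))
        report, _ = run_experiment(
            tables, "normal_abnormal", classifiers=("svm", "bogus"), seed=0
        )
        assert list(report["status"].str.startswith("failed")) == [False, True]
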