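"""Classifier benchmarking: six learners x five enhancement combinations.

The study design is a stratified 70/30 case-level split (paired views of
one subject never straddle the split) with leave-one-out cross-validation
available on the training split for model assessment; test-split metrics
form the report. Metrics follow the usual confusion-table algebra —
accuracy, sensitivity, specificity, PPV, NPV, balanced accuracy, F1 — plus
the rank-based ROC AUC from continuous classifier scores. Ratios with a
zero denominator are reported as absent (None), never as 0.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, fields as dc_fields
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .select import rank_auc

log = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIERS",
    "ConfusionTable",
    "MetricSet",
    "split_cases",
    "train_classifier",
    "predict_scores",
    "loocv_scores",
    "evaluate",
    "run_experiment",
]

CLASSIFIERS = ("svm", "rf", "ann", "knn", "nb", "dt")
_SCALED = {"svm", "ann", "knn"}  # distance/gradient learners get train-fit scaling


@dataclass
class ConfusionTable:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricSet:
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    PPV: Optional[float]
    NPV: Optional[float]
    AUC: Optional[float]
    balanced_accuracy: Optional[float]
    F1: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def metrics_from_confusion(ct: ConfusionTable, auc: Optional[float] = None) -> MetricSet:
    """Confusion-table algebra; zero-denominator ratios come back as None."""
    sens = _ratio(ct.TP, ct.TP + ct.FN)
    spec = _ratio(ct.TN, ct.TN + ct.FP)
    ppv = _ratio(ct.TP, ct.TP + ct.FP)
    ba = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    f1 = (
        2.0 * ppv * sens / (ppv + sens)
        if ppv is not None and sens is not None and (ppv + sens) > 0
        else None
    )
    return MetricSet(
        accuracy=_ratio(ct.TP + ct.TN, ct.total),
        sensitivity=sens,
        specificity=spec,
        PPV=ppv,
        NPV=_ratio(ct.TN, ct.TN + ct.FN),
        AUC=auc,
        balanced_accuracy=ba,
        F1=f1,
    )


def _subject_of(case_id: str) -> str:
    """Strip a trailing laterality letter so paired views share a subject key."""
    return re.sub(r"[lr]$", "", case_id)


def split_cases(
    ids, labels, train_fraction: float = 0.70, seed: int = 0, subjects=None
) -> tuple[list, list]:
    """Stratified, subject-grouped train/test split, reproducible by seed.

    ``subjects`` defaults to the case id with any trailing l/r view letter
    removed, so the two views of one subject stay on the same side. A
    subject is positive if any of its cases is.
    """
    ids = list(ids)
    labels = np.asarray(labels).astype(int)
    if subjects is None:
        subjects = [_subject_of(i) for i in ids]
    subj_label: dict[str, int] = {}
    for s, y in zip(subjects, labels):
        subj_label[s] = max(subj_label.get(s, 0), int(y))
    classes = set(subj_label.values())
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    for c in classes:
        if sum(1 for v in subj_label.values() if v == c) < 2:
            raise ValueError(f"class {c} has fewer than 2 subjects")
    rng = np.random.default_rng(seed)
    train_subj: set[str] = set()
    for c in sorted(classes):
        members = sorted(s for s, v in subj_label.items() if v == c)
        perm = rng.permutation(len(members))
        n_train = int(round(train_fraction * len(members)))
        train_subj.update(members[i] for i in perm[:n_train])
    train_ids = [i for i, s in zip(ids, subjects) if s in train_subj]
    test_ids = [i for i, s in zip(ids, subjects) if s not in train_subj]
    return train_ids, test_ids


def _make_estimator(name: str, seed: int):
    if name == "svm":
        est = SVC(C=1.0, kernel="rbf", gamma="scale", random_state=seed)
    elif name == "rf":
        est = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    elif name == "ann":
        est = MLPClassifier(
            hidden_layer_sizes=(16,), max_iter=3000, random_state=seed
        )
    elif name == "knn":
        est = KNeighborsClassifier(n_neighbors=5)
    elif name == "nb":
        est = GaussianNB()
    elif name == "dt":
        est = DecisionTreeClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown classifier {name!r}: expected one of {CLASSIFIERS}")
    if name in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def train_classifier(name: str, X, y, seed: int = 0):
    """Fit one of the six learners; deterministic under a fixed seed.

    The returned model predicts classes and, via :func:`predict_scores`,
    continuous scores for ROC analysis.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels hold a single class")
    model = _make_estimator(name, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter on tiny folds
        model.fit(X, y)
    return model


def predict_scores(model, X) -> np.ndarray:
    """Continuous scores for the positive class (decision function when
    available, positive-class probability otherwise)."""
    X = np.asarray(X, dtype=np.float64)
    if hasattr(model, "decision_function"):
        try:
            return np.asarray(model.decision_function(X), dtype=np.float64)
        except AttributeError:  # pipeline whose final step lacks it
            pass
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    return np.asarray(proba[:, classes.index(1)], dtype=np.float64)


def loocv_scores(name: str, X, y, seed: int = 0) -> np.ndarray:
    """Leave-one-out out-of-fold scores on the training table (n fits)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 cases")
    scores = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        yi = y[keep]
        if len(np.unique(yi)) < 2:
            warnings.warn(f"fold {i}: single-class training fold")
            scores[i] = 0.0
            continue
        model = train_classifier(name, X[keep], yi, seed)
        scores[i] = predict_scores(model, X[i : i + 1])[0]
    return scores


def evaluate(model, X, y) -> tuple[ConfusionTable, MetricSet]:
    """Confusion table and metric set on held-out cases (positive label 1)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    pred = np.asarray(model.predict(X)).astype(int)
    ct = ConfusionTable(
        TP=int(np.sum((pred == 1) & (y == 1))),
        FP=int(np.sum((pred == 1) & (y == 0))),
        TN=int(np.sum((pred == 0) & (y == 0))),
        FN=int(np.sum((pred == 0) & (y == 1))),
    )
    auc = None
    if len(np.unique(y)) == 2:
        auc = rank_auc(predict_scores(model, X), y)
    return ct, metrics_from_confusion(ct, auc)


def _task_labels(feature_table: pd.DataFrame, task: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Restrict rows and derive the binary label for a task.

    normal_abnormal: all cases, positive = abnormal.
    benign_malign: abnormal cases only, positive = malign.
    """
    if task == "normal_abnormal":
        sub = feature_table
        y = (sub["tissue_class"] == "abnormal").to_numpy().astype(int)
    elif task == "benign_malign":
        sub = feature_table[feature_table["tissue_class"] == "abnormal"]
        y = (sub["severity"] == "malign").to_numpy().astype(int)
    else:
        raise ValueError("task must be normal_abnormal|benign_malign")
    return sub, y


def run_experiment(
    feature_tables: dict[str, pd.DataFrame],
    task: str = "normal_abnormal",
    classifiers=CLASSIFIERS,
    seed: int = 0,
    selection_mode: str = "corr",
    selection_threshold: float = 0.90,
    train_fraction: float = 0.70,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full factorial evaluation over combos x classifiers for one task.

    ``feature_tables`` maps combo name -> table with columns id,
    tissue_class, severity and the 33 features (one row per case). Feature
    selection (correlation filter on the training split, or the fixed
    nine-feature preset) happens per combo; the split is shared across
    combos so rows are comparable. Returns the metric report (one row per
    classifier x combo) and the AUC plot table. A failed cell is marked
    failed and the run continues.
    """
    from .select import apply_reference_preset, correlation_filter
    from .texture import FEATURE_NAMES

    rows = []
    for combo, table in feature_tables.items():
        sub, y = _task_labels(table, task)
        ids = sub["id"].tolist()
        train_ids, test_ids = split_cases(ids, y, train_fraction, seed)
        in_train = sub["id"].isin(train_ids).to_numpy()
        feats = sub[[c for c in FEATURE_NAMES if c in sub.columns]]
        if selection_mode == "preset":
            feats = apply_reference_preset(feats)
            kept = list(feats.columns)
        elif selection_mode == "corr":
            sel = correlation_filter(feats[in_train], selection_threshold)
            kept = sel.retained
        elif selection_mode == "none":
            kept = list(feats.columns)
        else:
            raise ValueError("selection_mode must be corr|preset|none")
        Xtr, ytr = feats.loc[in_train, kept].to_numpy(), y[in_train]
        Xte, yte = feats.loc[~in_train, kept].to_numpy(), y[~in_train]
        for name in classifiers:
            row = {"classifier": name, "combo": combo, "task": task,
                   "n_train": len(ytr), "n_test": len(yte),
                   "n_features": len(kept), "status": "ok"}
            try:
                model = train_classifier(name, Xtr, ytr, seed)
                _, ms = evaluate(model, Xte, yte)
                row.update(ms.as_dict())
            except Exception as exc:  # keep the factorial loop alive
                log.warning("%s x %s failed: %s", name, combo, exc)
                row["status"] = f"failed: {exc}"
            rows.append(row)
    report = pd.DataFrame(rows)
    plot_data = report.pivot_table(index="combo", columns="classifier", values="AUC")
    return report, plot_data


def plot_auc_comparison(plot_data: pd.DataFrame, path) -> None:
    """Grouped bar chart of AUC per (combo, classifier), saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = plot_data.plot.bar(rot=0, figsize=(9, 4.5))
    ax.set_ylabel("AUC")
    ax.set_ylim(0, 1.05)
    ax.set_xlabel("pre-processing combination")
    ax.legend(title="classifier", ncols=3, fontsize=8)
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)
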