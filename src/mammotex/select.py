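"""Correlation-based feature elimination and per-feature ROC screening.

Redundant features are removed by a greedy scan in the canonical feature
order: a feature is dropped when its absolute Pearson correlation with any
already-retained feature exceeds the threshold (0.90 by default) —
anticorrelated duplicates are just as redundant as correlated ones, hence
the absolute value. Each surviving feature can then be screened on its own
with the rank-based (midrank Mann–Whitney) ROC AUC; AUCs are reported
orientation-free as max(A, 1 - A) with a direction flag.

The nine-feature reference preset keeps a fixed subset
(GLCM autocorrelation, contrast, cluster prominence, entropy; GLRLM short
run emphasis, long run emphasis, gray-level non-uniformity, short run low
gray-level emphasis, long run low gray-level emphasis) in that order,
bypassing data-driven selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SelectionResult",
    "REFERENCE_NINE_FEATURES",
    "correlation_filter",
    "per_feature_auc",
    "rank_auc",
    "apply_reference_preset",
]

#: the fixed nine-feature reference subset, in its canonical order
REFERENCE_NINE_FEATURES = [
    "glcm_autocorrelation",
    "glcm_contrast",
    "glcm_cluster_prominence",
    "glcm_entropy",
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_gln",
    "glrlm_srlge",
    "glrlm_lrlge",
]


@dataclass
class SelectionResult:
    retained: list[str]
    dropped: list[tuple[str, str, float]]  # (dropped, kept partner, r)
    threshold: float
    per_feature_auc: dict[str, float] = field(default_factory=dict)
    auc_direction: dict[str, int] = field(default_factory=dict)  # +1 high=positive


def correlation_filter(table: pd.DataFrame, threshold: float = 0.90) -> SelectionResult:
    """Greedy keep-first elimination of |Pearson r| > threshold pairs.

    Columns are scanned in the table's column order; a column is dropped if
    it correlates beyond the threshold with any already-retained column.
    Constant columns have undefined r, are treated as r = 0 and retained
    with a warning.
    """
    if not 0 < threshold <= 1:
        raise ValueError("correlation threshold must be in (0, 1]")
    if len(table) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    X = table.to_numpy(dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("feature table contains missing/non-finite values")
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"constant column(s) treated as r=0: {list(table.columns[const])}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    retained: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for jcol in range(X.shape[1]):
        partner = next(
            (k for k in retained if abs(corr[jcol, k]) > threshold), None
        )
        if partner is None:
            retained.append(jcol)
        else:
            dropped.append(
                (table.columns[jcol], table.columns[partner], float(corr[jcol, partner]))
            )
    return SelectionResult(
        retained=[table.columns[j] for j in retained],
        dropped=dropped,
        threshold=threshold,
    )


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the midrank Mann–Whitney statistic (positive label = 1)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # midranks for ties
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def per_feature_auc(table: pd.DataFrame, labels) -> tuple[dict[str, float], dict[str, int]]:
    """Orientation-free single-feature AUCs against a binary label.

    Returns (auc, direction) maps; direction +1 means larger values score
    the positive class, -1 the reverse.
    """
    labels = np.asarray(labels).astype(int)
    aucs: dict[str, float] = {}
    direction: dict[str, int] = {}
    for col in table.columns:
        a = rank_auc(table[col].to_numpy(), labels)
        direction[col] = 1 if a >= 0.5 else -1
        aucs[col] = max(a, 1.0 - a)
    return aucs, direction


def apply_reference_preset(table: pd.DataFrame) -> pd.DataFrame:
    """Reduce a feature table to the fixed nine-feature reference subset, in order."""
    missing = [c for c in REFERENCE_NINE_FEATURES if c not in table.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    return table[REFERENCE_NINE_FEATURES].copy()
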