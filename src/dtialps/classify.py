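"""SVM disease classification with repeated-split ROC evaluation.

Protocol: for each group pair (NC vs MCI, MCI vs AD, NC vs AD) and each
feature set (ALPS indices, ROI-mean FA, or their combination), repeat a
stratified 4:1 train/test split; on the training 80% a 5-fold
cross-validation selects the SVM regularization constant from a fixed
grid; the model is refit on the full training portion and its decision
scores on the held-out 20% give one ROC/AUC. The mean AUC over repeats
(default 100) and its 2.5/97.5 percentile interval summarize performance.
Feature standardization is estimated on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FEATURE_SETS",
    "DEFAULT_PAIRS",
    "ClassificationResult",
    "build_features",
    "roc_auc",
    "svm_repeated_eval",
    "run_classification",
]

#: Feature-set vocabulary -> cohort columns
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "FA": ("FA_mean",),
    "ALPS_L": ("L_ALPS",),
    "ALPS_R": ("R_ALPS",),
    "ALPS_Bi": ("Bi_ALPS",),
    "FA+ALPS_L": ("FA_mean", "L_ALPS"),
    "FA+ALPS_R": ("FA_mean", "R_ALPS"),
    "FA+ALPS_Bi": ("FA_mean", "Bi_ALPS"),
}

DEFAULT_PAIRS = (("NC", "MCI"), ("MCI", "AD"), ("NC", "AD"))
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class ClassificationResult:
    """Repeated-split evaluation summary for one (pair, feature set)."""

    pair: str
    feature_set: str
    aucs: np.ndarray  # one test AUC per repeat
    mean_auc: float
    ci_low: float
    ci_high: float
    chosen_c: list[float]  # CV-selected regularization per repeat
    roc_points: np.ndarray  # pooled (fpr, tpr) curve over all repeats' test scores
    n_subjects: int
    n_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "pair": self.pair,
            "feature_set": self.feature_set,
            "mean_auc": self.mean_auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_repeats": int(self.aucs.shape[0]),
            "n_subjects": self.n_subjects,
            "n_dropped": self.n_dropped,
            "aucs": [float(a) for a in self.aucs],
            "chosen_c": self.chosen_c,
        }


def build_features(
    cohort: pd.DataFrame, feature_set: str, pair: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Feature matrix and 0/1 labels for one group pair.

    Rows with missing features are dropped (count returned). Labels: the
    second group of the pair codes as 1. Standardization happens inside
    the evaluation pipeline (training folds only), not here.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; options: {sorted(FEATURE_SETS)}")
    cols = list(FEATURE_SETS[feature_set])
    sub = cohort[cohort["group"].isin(pair)]
    for grp in pair:
        if (sub["group"] == grp).sum() < 10:
            raise ValueError(f"group {grp!r} has fewer than 10 subjects")
    complete = sub.dropna(subset=cols)
    n_dropped = len(sub) - len(complete)
    y = (complete["group"] == pair[1]).to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class data after filtering")
    X = complete[cols].to_numpy(dtype=float)
    return X, y, n_dropped


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUC (Mann-Whitney form, ties as 1/2) and (FPR, TPR) curve points."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    classes = np.unique(labels)
    if classes.shape[0] != 2:
        raise ValueError("roc_auc needs exactly two classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, np.column_stack([fpr, tpr])


def svm_repeated_eval(
    X,
    y,
    n_repeats: int = 100,
    test_fraction: float = 0.2,
    cv_folds: int = 5,
    c_grid=DEFAULT_C_GRID,
    kernel: str = "linear",
    seed: int = 0,
    pair: str = "",
    feature_set: str = "",
) -> ClassificationResult:
    """Repeated stratified-split SVM evaluation with in-loop CV model selection.

    All randomness flows from ``seed``: per-repeat split and CV seeds are
    drawn deterministically, so results are bit-reproducible.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    min_class = np.bincount(y.astype(int)).min()
    if min_class < cv_folds:
        raise ValueError(
            f"smallest class (n={min_class}) too small for {cv_folds}-fold CV"
        )
    rng = np.random.default_rng(seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)

    aucs = np.empty(n_repeats)
    chosen = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for rep, rs in enumerate(repeat_seeds):
        rs = int(rs)
        train_idx = test_idx = None
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=test_fraction, random_state=rs % (2**32 - 1)
        )
        for attempt in range(10):
            tr, te = next(splitter.split(X, y))
            if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2:
                train_idx, test_idx = tr, te
                break
            splitter = StratifiedShuffleSplit(
                n_splits=1, test_size=test_fraction, random_state=(rs + attempt + 1) % (2**32 - 1)
            )
        if train_idx is None:
            raise RuntimeError("could not draw a two-class split in 10 attempts")

        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=kernel)),
        ])
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rs % (2**32 - 1))
        search = GridSearchCV(
            pipe, {"svm__C": list(c_grid)}, scoring="roc_auc", cv=cv, refit=True
        )
        search.fit(X[train_idx], y[train_idx])
        scores = search.decision_function(X[test_idx])
        aucs[rep] = roc_auc_score(y[test_idx], scores)
        chosen.append(float(search.best_params_["svm__C"]))
        pooled_scores.append(scores)
        pooled_labels.append(y[test_idx])

    all_scores = np.concatenate(pooled_scores)
    all_labels = np.concatenate(pooled_labels)
    _, curve = roc_auc(all_scores, all_labels)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return ClassificationResult(
        pair=pair,
        feature_set=feature_set,
        aucs=aucs,
        mean_auc=float(aucs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        chosen_c=chosen,
        roc_points=curve,
        n_subjects=int(X.shape[0]),
    )


def run_classification(
    cohort: pd.DataFrame,
    pairs=DEFAULT_PAIRS,
    feature_sets=tuple(FEATURE_SETS),
    n_repeats: int = 100,
    seed: int = 0,
    **eval_kwargs,
) -> list[ClassificationResult]:
    """Evaluate every (pair, feature set) combination on a cohort table.

    Per-combination seeds are derived deterministically from ``seed``.
    """
    results = []
    for i, pair in enumerate(pairs):
        for j, fs in enumerate(feature_sets):
            X, y, n_dropped = build_features(cohort, fs, tuple(pair))
            res = svm_repeated_eval(
                X, y, n_repeats=n_repeats,
                seed=(seed * 1_000_003 + i * 101 + j) % (2**31 - 1),
                pair=f"{pair[0]}_vs_{pair[1]}", feature_set=fs, **eval_kwargs,
            )
            res.n_dropped = n_dropped
            results.append(res)
    return results
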