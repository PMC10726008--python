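"""Supervised classification of subspecies from aligned peak features.

Covers the modelling stage end to end: grouped/stratified 70/30 split,
Min-Max scaling (train statistics only), recursive feature elimination
with stratified 5-fold cross-validation on an L2 logistic-regression base
learner, LR / SVM / RF training with probability-like scores for the
infantis class, ROC/AUC evaluation with a Youden-index operating
threshold, and permutation feature importance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import inspection
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

from maldisub.align import FeatureMatrix

CLASSIFIER_KINDS = ("LR", "SVM", "RF")


@dataclass
class SplitSpec:
    """Train/test split parameters (70/30, grouped by strain, stratified)."""

    train_frac: float = 0.7
    group_by_strain: bool = True
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_frac < 1.0):
            raise ValueError(f"train_frac must lie in (0, 1); got {self.train_frac}")


@dataclass
class ModelReport:
    """Evaluation summary for one classifier."""

    classifier_kind: str
    selected_features: list[str]
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden: float
    auc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    cv_curve: list[float] = field(default_factory=list)
    grouped_split: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def split_dataset(fm: FeatureMatrix, spec: SplitSpec) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Split a labeled feature matrix into train and test sets.

    With ``group_by_strain`` all replicates of a strain travel together
    (no replicate leakage); stratification allocates ``train_frac`` of each
    class's strains (rounded) to training. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    strain_labels = fm.strain_labels()
    for cls in (0, 1):
        if (strain_labels == cls).sum() < 2:
            raise ValueError(f"need at least 2 strains of class {cls} to split")
    if spec.group_by_strain:
        train_ids: list[str] = []
        if spec.stratify:
            for cls in (0, 1):
                ids = strain_labels.index[strain_labels == cls].to_numpy()
                ids = ids[rng.permutation(ids.size)]
                n_train = int(round(spec.train_frac * ids.size))
                n_train = min(max(n_train, 1), ids.size - 1)
                train_ids.extend(ids[:n_train])
        else:
            ids = strain_labels.index.to_numpy()
            ids = ids[rng.permutation(ids.size)]
            n_train = min(max(int(round(spec.train_frac * ids.size)), 1), ids.size - 1)
            train_ids.extend(ids[:n_train])
        train_set = set(train_ids)
        mask = fm.presence.index.get_level_values("strain_id").isin(train_set)
        return fm.subset_rows(mask), fm.subset_rows(~mask)
    # spectrum-level split (risks replicate leakage; supported for comparison)
    y = fm.labels.to_numpy()
    mask = np.zeros(y.size, dtype=bool)
    classes = (0, 1) if spec.stratify else (None,)
    for cls in classes:
        idx = np.arange(y.size) if cls is None else np.nonzero(y == cls)[0]
        idx = idx[rng.permutation(idx.size)]
        n_train = min(max(int(round(spec.train_frac * idx.size)), 1), idx.size - 1)
        mask[idx[:n_train]] = True
    return fm.subset_rows(mask), fm.subset_rows(~mask)


def scale_minmax(
    train_features: pd.DataFrame | np.ndarray,
    other_features: pd.DataFrame | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None, dict]:
    """Min-Max scale features using training-set statistics only.

    Each feature maps to (x - min) / (max - min) with min and max taken from
    the training set; a constant training feature maps to 0 everywhere
    (train and other). Values outside the training range are not clipped.
    Returns (scaled train, scaled other or None, params with 'min'/'scale').
    """
    tr = np.asarray(train_features, dtype=float)
    if tr.size == 0:
        raise ValueError("train_features must be non-empty")
    mn = tr.min(axis=0)
    mx = tr.max(axis=0)
    rng_ = mx - mn
    scale = np.where(rng_ > 0, 1.0 / np.where(rng_ > 0, rng_, 1.0), 0.0)
    scaled_train = (tr - mn) * scale
    scaled_other = None
    if other_features is not None:
        scaled_other = (np.asarray(other_features, dtype=float) - mn) * scale
    return scaled_train, scaled_other, {"min": mn, "scale": scale}


def _elimination_order(X: np.ndarray, y: np.ndarray, step: int) -> list[int]:
    """Recursive feature elimination order: repeatedly fit L2 logistic
    regression and drop the ``step`` features with smallest |coefficient|.
    Returns feature indices from first-dropped to last-surviving."""
    remaining = list(range(X.shape[1]))
    dropped: list[int] = []
    while len(remaining) > 1:
        clf = LogisticRegression(max_iter=2000)
        clf.fit(X[:, remaining], y)
        coefs = np.abs(clf.coef_[0])
        k = min(step, len(remaining) - 1)
        worst = np.argsort(coefs, kind="stable")[:k]
        for w in sorted(worst, reverse=True):
            dropped.append(remaining.pop(int(w)))
    dropped.extend(remaining)
    return dropped


def rfecv_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    step: int = 1,
    folds: int = 5,
) -> tuple[list[str], list[float]]:
    """Recursive feature elimination with stratified k-fold cross-validation.

    Within each fold, an elimination path is built by iteratively dropping
    the feature with the smallest |coefficient| of an L2 logistic
    regression fit on scaled features; the fold's held-out accuracy is then
    recorded for every subset size along that path. The returned subset is
    the elimination-path prefix (fit on all of X) of the size whose mean CV
    accuracy is maximal, ties going to the smaller size.

    Returns (selected feature names, cv_curve with mean accuracy per size
    1..n_features).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_feat = X.shape[1]
    if feature_names is None:
        feature_names = [str(i) for i in range(n_feat)]
    if n_feat == 1:
        clf = LogisticRegression(max_iter=2000).fit(X, y)
        return list(feature_names), [float(clf.score(X, y))]
    for cls in np.unique(y):
        if (y == cls).sum() < folds:
            raise ValueError(f"need at least {folds} samples per class for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=False)
    scores = np.zeros((folds, n_feat))
    for f, (tr_idx, te_idx) in enumerate(skf.split(X, y)):
        order = _elimination_order(X[tr_idx], y[tr_idx], step)
        for size in range(1, n_feat + 1):
            keep = order[-size:]
            clf = LogisticRegression(max_iter=2000)
            clf.fit(X[np.ix_(tr_idx, keep)], y[tr_idx])
            scores[f, size - 1] = clf.score(X[np.ix_(te_idx, keep)], y[te_idx])
    cv_curve = scores.mean(axis=0)
    best_size = int(np.argmax(cv_curve)) + 1  # argmax takes the first (smallest) on ties
    full_order = _elimination_order(X, y, step)
    selected_idx = sorted(full_order[-best_size:])
    return [feature_names[i] for i in selected_idx], [float(v) for v in cv_curve]


def fit_predict(
    kind: str,
    train_X: np.ndarray,
    train_y: np.ndarray,
    eval_X: np.ndarray,
    seed: int = 0,
):
    """Fit one classifier and score an evaluation set.

    Scores are the probability-like score of the infantis class (label 1):
    predicted probabilities for LR and RF, and a Platt-calibrated sigmoid
    mapping of the decision function for the RBF SVM. Deterministic per
    seed. Returns (scores, fitted model).
    """
    if kind == "LR":
        model = LogisticRegression(max_iter=2000)
    elif kind == "SVM":
        model = SVC(kernel="rbf", probability=True, random_state=seed)
    elif kind == "RF":
        model = RandomForestClassifier(n_estimators=200, random_state=seed)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; expected one of {CLASSIFIER_KINDS}")
    model.fit(np.asarray(train_X, dtype=float), np.asarray(train_y))
    scores = model.predict_proba(np.asarray(eval_X, dtype=float))[:, 1]
    return scores, model


def evaluate_scores(scores, labels, threshold: float | None = None) -> ModelReport:
    """ROC evaluation with a Youden operating point.

    The ROC curve is a threshold sweep; AUC by the trapezoid rule. When no
    threshold is given, the operating cutoff is the score value maximizing
    the Youden index (tpr - fpr) on these scores, with ties resolved toward
    the higher cutoff. With infantis (1) positive: sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), youden = sensitivity + specificity - 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("evaluate_scores needs both classes present in labels")
    fpr, tpr, _thr = roc_curve(labels, scores)
    auc_val = float(trapezoid_auc(fpr, tpr))
    if threshold is None:
        best_j, threshold = -np.inf, float(scores.max())
        for t in np.unique(scores)[::-1]:
            pred = scores >= t
            tp = int(np.sum(pred & (labels == 1)))
            fn = int(np.sum(~pred & (labels == 1)))
            tn = int(np.sum(~pred & (labels == 0)))
            fp = int(np.sum(pred & (labels == 0)))
            j = tp / (tp + fn) - fp / (fp + tn)
            if j > best_j:
                best_j, threshold = j, float(t)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / labels.size
    return ModelReport(
        classifier_kind="",
        selected_features=[],
        threshold=float(threshold),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        youden=sens + spec - 1.0,
        auc=auc_val,
        roc_points=[(float(a), float(b)) for a, b in zip(fpr, tpr)],
    )


def youden_threshold_cv(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    groups=None,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Operating threshold learned on training data via cross-validation.

    Resubstitution scores of a well-fit classifier pile up near 0 and 1, so
    a Youden cutoff taken from them is badly calibrated for unseen spectra.
    Instead, out-of-fold scores are collected over a stratified k-fold split
    (grouped when ``groups`` — e.g. strain ids — are given, so replicates of
    one strain never straddle a fold boundary) and the Youden-optimal cutoff
    of those held-out scores is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=False)
        split_iter = splitter.split(X, y)
    oof = np.zeros(y.size)
    for tr_idx, te_idx in split_iter:
        scores, _model = fit_predict(kind, X[tr_idx], y[tr_idx], X[te_idx], seed=seed)
        oof[te_idx] = scores
    return evaluate_scores(oof, y).threshold


def permutation_importance(
    model,
    eval_X: np.ndarray,
    eval_y: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Mean AUC drop per feature over label-preserving column shuffles."""
    result = inspection.permutation_importance(
        model,
        np.asarray(eval_X, dtype=float),
        np.asarray(eval_y),
        scoring="roc_auc",
        n_repeats=n_repeats,
        random_state=seed,
    )
    return result.importances_mean
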