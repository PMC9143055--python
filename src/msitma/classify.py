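"""Cost-sensitive classification of TMA cores.

A weighted (cost-sensitive) L2-regularised logistic regression is fitted on
per-core average spectra, with inverse-frequency class weights countering the
strong tumour:normal imbalance, and evaluated by stratified K-fold (K=10)
cross-validation whose folds are additionally constrained so every test fold
draws cores from at least two slides — otherwise a fold could conflate the
class effect with a slide batch effect.  Metrics follow the usual confusion
conventions (TPR, TNR, FPR, balanced accuracy, F1) plus ROC-AUC; a PCA +
Mann-Whitney analysis quantifies unsupervised class separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .io import MassAxis
from .cores import CoreTable

__all__ = [
    "CoreFeatureTable",
    "FitResult",
    "MetricSet",
    "CVResult",
    "ROCResult",
    "PCASeparationResult",
    "core_feature_table",
    "class_weights",
    "fit_weighted_lr",
    "slide_aware_stratified_folds",
    "cross_validate",
    "compute_metrics",
    "roc_curve",
    "pca_separation",
]


@dataclass
class CoreFeatureTable:
    """Design matrix for core classification (reference cores excluded)."""

    X: np.ndarray
    y: np.ndarray  # 1 = tumour, 0 = normal
    slide_ids: np.ndarray
    patient_ids: np.ndarray
    axis: MassAxis

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValidationError("X and y are inconsistent")
        if set(np.unique(self.y)) != {0, 1}:
            raise ValidationError("both classes must be present")
        if np.any(self.X < 0):
            raise ValidationError("feature matrix must be non-negative")

    @property
    def n_cores(self) -> int:
        return int(self.y.size)

    @property
    def n_features(self) -> int:
        return int(self.X.shape[1])

    def subset_features(self, indices) -> "CoreFeatureTable":
        idx = np.asarray(indices, dtype=int)
        return CoreFeatureTable(self.X[:, idx], self.y, self.slide_ids, self.patient_ids,
                                MassAxis(self.axis.mz[idx]))


def core_feature_table(table: CoreTable) -> CoreFeatureTable:
    """Build the classification table from a core table (drops reference cores)."""
    keep = table.meta["label"].isin(["tumour", "normal"]).to_numpy()
    meta = table.meta[keep]
    y = (meta["label"] == "tumour").to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValidationError("both tumour and normal cores are required")
    return CoreFeatureTable(table.spectra[keep], y, meta["slide_id"].to_numpy(object),
                            meta["patient_id"].to_numpy(object), table.axis)


def class_weights(y: np.ndarray) -> dict:
    """Inverse-frequency class weights, ``n_total / (2 * n_class)``.

    Balanced data gives both classes weight 1; the minority class is
    up-weighted in proportion to the imbalance.
    """
    y = np.asarray(y, dtype=int)
    counts = {c: int((y == c).sum()) for c in (0, 1)}
    if counts[0] == 0 or counts[1] == 0:
        raise ValidationError("class weights require both classes to be present")
    return {c: y.size / (2.0 * n) for c, n in counts.items()}


def sample_weights(y: np.ndarray) -> np.ndarray:
    w = class_weights(y)
    return np.asarray([w[int(c)] for c in y])


@dataclass
class FitResult:
    """A fitted weighted logistic regression.

    Coefficients are reported in the internally standardised feature space
    (mean 0, sd 1 per feature on the training data); ``coefficients_original``
    maps them back to raw intensity units.  The objective is the weighted
    log-likelihood minus an L2 penalty of ``regularization_strength/2 * ||b||^2``
    (convex, so the fit is deterministic).
    """

    coefficients: np.ndarray
    intercept: float
    class_weights: dict
    regularization_strength: float
    converged: bool
    log_likelihood: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray

    @property
    def coefficients_original(self) -> np.ndarray:
        return self.coefficients / self.scaler_scale

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale
        return Z @ self.coefficients + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        from scipy.special import expit
        return expit(self.decision_function(X))

    def feature_ranking(self) -> np.ndarray:
        """Feature indices ordered by decreasing |standardised coefficient|."""
        return np.argsort(-np.abs(self.coefficients), kind="stable")


def fit_weighted_lr(X: np.ndarray, y: np.ndarray, sample_weights: np.ndarray | None = None,
                    regularization_strength: float = 1e-2, max_iter: int = 1000) -> FitResult:
    """Fit a weighted L2-regularised logistic regression.

    Features are standardised internally; the stored transform is re-applied
    at prediction time.  With no explicit sample weights, inverse-frequency
    class weights are used.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature matrix must be finite")
    cw = class_weights(y)
    if sample_weights is None:
        sample_weights = np.asarray([cw[int(c)] for c in y])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - mean) / scale

    clf = LogisticRegression(C=1.0 / regularization_strength,  # default penalty: L2
                             solver="lbfgs", tol=1e-6, max_iter=max_iter)
    clf.fit(Z, y, sample_weight=sample_weights)
    coef = clf.coef_.ravel()
    intercept = float(clf.intercept_[0])
    eta = Z @ coef + intercept
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = float(np.sum(sample_weights * (y * np.log(p) + (1 - y) * np.log(1 - p))))
    converged = bool(np.all(clf.n_iter_ < max_iter))
    return FitResult(coef, intercept, cw, regularization_strength, converged, ll, mean, scale)


def slide_aware_stratified_folds(y: np.ndarray, slide_ids: np.ndarray, n_splits: int = 10,
                                 seed: int = 0) -> np.ndarray:
    """Class-stratified K folds whose test sets each span at least two slides.

    Folds are first stratified on class; test cores are then greedily swapped
    between folds (within class, lowest indices first) until every fold's test
    set contains cores from at least two distinct slides — the cross-validation
    reading of "minimising slide-to-slide bias".  Deterministic under ``seed``.
    """
    y = np.asarray(y, dtype=int)
    slide_ids = np.asarray(slide_ids, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("stratified folds require both classes")
    if n_splits > counts.min():
        raise ValidationError(
            f"K={n_splits} exceeds the minority class count ({counts.min()})")
    n_slides = np.unique(slide_ids).size
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=int)
    for k, (_, test) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        assignment[test] = k

    if n_slides >= 2:
        for k in range(n_splits):
            for _ in range(y.size):  # bounded repair loop
                test_k = np.flatnonzero(assignment == k)
                slides_k = set(slide_ids[test_k])
                if len(slides_k) >= 2:
                    break
                swapped = False
                for j in np.flatnonzero(assignment != k):  # deterministic index order
                    if slide_ids[j] in slides_k:
                        continue
                    g = assignment[j]
                    test_g = np.flatnonzero(assignment == g)
                    partners = [i for i in test_k if y[i] == y[j]]
                    if not partners:
                        continue
                    i = partners[0]
                    # fold g must keep >= 2 slides after giving j away
                    remaining = set(slide_ids[test_g]) - {slide_ids[j]} | {slide_ids[i]}
                    if len(test_g) > 1 and len(remaining) < 2:
                        continue
                    assignment[i], assignment[j] = g, k
                    swapped = True
                    break
                if not swapped:
                    raise ValidationError(
                        f"cannot construct folds where test fold {k} spans >= 2 slides")
        for k in range(n_splits):
            if len(set(slide_ids[assignment == k])) < 2:
                raise ValidationError(
                    f"cannot construct folds where test fold {k} spans >= 2 slides")
    for k in range(n_splits):
        train_y = y[assignment != k]
        if np.unique(train_y).size < 2:
            raise ValidationError(f"training set of fold {k} is missing a class")
    return assignment


@dataclass
class MetricSet:
    tpr: float
    tnr: float
    fpr: float
    balanced_accuracy: float
    f1: float

    def to_dict(self) -> dict:
        return {"tpr": self.tpr, "tnr": self.tnr, "fpr": self.fpr,
                "balanced_accuracy": self.balanced_accuracy, "f1": self.f1}


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricSet:
    """Confusion-count metrics: TPR, TNR, FPR, balanced accuracy, F1."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValidationError(f"{name} must be non-negative")
    if tp + fn == 0:
        raise ValidationError("no positive-class examples (tp + fn = 0)")
    if tn + fp == 0:
        raise ValidationError("no negative-class examples (tn + fp = 0)")
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    fpr = fp / (tn + fp)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return MetricSet(tpr, tnr, fpr, (tpr + tnr) / 2.0, f1)


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds})


def roc_curve(y: np.ndarray, probabilities: np.ndarray) -> ROCResult:
    """ROC curve over all unique probability thresholds, AUC by trapezoid.

    The trapezoid AUC of the full step curve equals the Mann-Whitney
    concordance probability (ties counted 1/2) exactly.
    """
    y = np.asarray(y, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if np.unique(y).size < 2:
        raise ValidationError("ROC requires both classes")
    fpr, tpr, thr = _sk_roc_curve(y, p, drop_intermediate=False)
    return ROCResult(fpr, tpr, thr, float(_trapezoid_auc(fpr, tpr)))


@dataclass
class CVResult:
    """Out-of-fold cross-validation result of the core classifier."""

    fold_assignment: np.ndarray
    oof_probability: np.ndarray
    confusion: tuple  # (TP, FP, TN, FN) at threshold 0.5
    metrics: MetricSet
    roc: ROCResult

    def to_dict(self) -> dict:
        tp, fp, tn, fn = self.confusion
        return {"confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
                "metrics": self.metrics.to_dict(), "auc": self.roc.auc,
                "n_folds": int(self.fold_assignment.max()) + 1,
                "n_cores": int(self.fold_assignment.size)}


def cross_validate(table: CoreFeatureTable, n_splits: int = 10, seed: int = 0,
                   regularization_strength: float = 1e-2,
                   folds: np.ndarray | None = None, threshold: float = 0.5) -> CVResult:
    """Slide-aware stratified K-fold cross-validation of the weighted LR.

    Standardisation and class weights are recomputed within each training
    fold; held-out probabilities are collected out-of-fold and summarised by a
    confusion matrix at ``threshold``, the metric set, and the ROC curve.
    """
    if folds is None:
        folds = slide_aware_stratified_folds(table.y, table.slide_ids, n_splits, seed)
    folds = np.asarray(folds, dtype=int)
    oof = np.full(table.n_cores, np.nan)
    for k in np.unique(folds):
        train = folds != k
        fit = fit_weighted_lr(table.X[train], table.y[train],
                              regularization_strength=regularization_strength)
        oof[folds == k] = fit.predict_proba(table.X[folds == k])
    pred = (oof >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (table.y == 1)))
    fp = int(np.sum((pred == 1) & (table.y == 0)))
    tn = int(np.sum((pred == 0) & (table.y == 0)))
    fn = int(np.sum((pred == 0) & (table.y == 1)))
    return CVResult(folds, oof, (tp, fp, tn, fn), compute_metrics(tp, fp, tn, fn),
                    roc_curve(table.y, oof))


@dataclass
class PCASeparationResult:
    scores: np.ndarray  # cores x components
    explained_variance_ratio: np.ndarray
    u_statistics: np.ndarray  # per component, min-rank convention
    p_values: np.ndarray  # two-tailed


def pca_separation(table: CoreFeatureTable, n_components: int = 3) -> PCASeparationResult:
    """PCA on mean-centred core spectra plus per-component Mann-Whitney tests.

    The U statistic is reported in the "min-rank" convention, ``min(U1, U2)``
    (complete separation gives 0); the two-tailed p-value uses exact
    enumeration for small samples (combined n <= 20, no ties) and the
    continuity-corrected normal approximation otherwise.
    """
    if table.n_cores < n_components + 1:
        raise ValidationError("need at least n_components + 1 cores")
    X = table.X - table.X.mean(axis=0)
    if np.allclose(X, 0):
        raise ValidationError("constant feature matrix has no principal components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    u_stats, p_values = [], []
    for j in range(scores.shape[1]):
        a = scores[table.y == 1, j]
        b = scores[table.y == 0, j]
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        u1 = float(res.statistic)
        u_stats.append(min(u1, a.size * b.size - u1))
        p_values.append(float(res.pvalue))
    return PCASeparationResult(scores, pca.explained_variance_ratio_,
                               np.asarray(u_stats), np.asarray(p_values))
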