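"""Two-pronged feature refinement for the core classifier.

Every spectral feature is screened twice: a per-feature likelihood-ratio test
(single-feature weighted logistic regression against the intercept-only
model, chi-square with 1 df) captures its multivariate/classification value,
and a Kruskal-Wallis rank test with Benjamini-Hochberg FDR correction
captures the univariate intensity difference.  Features significant under
both screens (LRT p < alpha and BH q < alpha) form the refined panel, and the
reduced model is re-cross-validated on the same folds as the full model so
the two are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import ValidationError
from .classify import CoreFeatureTable, CVResult, cross_validate, sample_weights, \
    slide_aware_stratified_folds

__all__ = [
    "FeatureSelectionResult",
    "SelectionRefitResult",
    "lrt_per_feature",
    "kruskal_wallis_per_feature",
    "bh_adjust",
    "select_features",
    "select_and_refit",
]


def _weighted_logistic_ll(x: np.ndarray | None, y: np.ndarray, w: np.ndarray,
                          max_iter: int = 50, tol: float = 1e-10) -> float:
    """Maximised weighted log-likelihood of logistic regression.

    ``x=None`` is the intercept-only model (closed form); otherwise a small
    Newton/IRLS solve with step halving for intercept + one feature.  Under
    complete separation the likelihood is evaluated at the iteration cap,
    which is as large as the test needs (the LRT statistic then dwarfs any
    chi-square quantile).
    """

    def ll(eta):
        p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        return float(np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))

    if x is None:
        phat = np.sum(w * y) / np.sum(w)
        phat = min(max(phat, 1e-12), 1 - 1e-12)
        return float(np.sum(w * (y * np.log(phat) + (1 - y) * np.log(1 - phat))))

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    current = ll(X @ beta)
    for _ in range(max_iter):
        eta = X @ beta
        p = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        grad = X.T @ (w * (y - p))
        W = w * p * (1 - p)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(2), grad)
        except np.linalg.LinAlgError:
            break
        # step halving: Newton can overshoot near separation
        for _ in range(30):
            candidate = beta + step
            new = ll(X @ candidate)
            if new >= current - 1e-12:
                break
            step = step / 2.0
        if new < current:
            break
        beta, improved, current = candidate, new - current, new
        if improved < tol:
            break
    return current


def lrt_per_feature(X: np.ndarray, y: np.ndarray, sample_weights: np.ndarray | None = None):
    """Per-feature likelihood-ratio test of single-feature LR vs intercept-only.

    The statistic is ``2 * (ll_feature - ll_intercept)`` with a chi-square
    (1 df) p-value; constant features score (0, 1).  Returns
    ``(statistics, p_values)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    w = np.ones(y.size) if sample_weights is None else np.asarray(sample_weights, dtype=float)
    if np.unique(y).size < 2:
        raise ValidationError("LRT requires both classes")
    ll0 = _weighted_logistic_ll(None, y, w)
    stats_out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        sd = col.std()
        if sd == 0:
            continue
        ll1 = _weighted_logistic_ll((col - col.mean()) / sd, y, w)
        stats_out[j] = max(2.0 * (ll1 - ll0), 0.0)
    p = stats.chi2.sf(stats_out, df=1)
    p[stats_out == 0] = 1.0
    return stats_out, p


def kruskal_wallis_per_feature(X: np.ndarray, y: np.ndarray):
    """Kruskal-Wallis H (tie-corrected) per feature between the two classes.

    With two groups H is a monotone transform of the Mann-Whitney U; p-values
    come from the chi-square distribution with 1 df.  Features whose values
    are all identical get (0, 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if (y == 0).sum() == 0 or (y == 1).sum() == 0:
        raise ValidationError("Kruskal-Wallis requires both classes")
    stats_out = np.zeros(X.shape[1])
    p_out = np.ones(X.shape[1])
    g0, g1 = y == 0, y == 1
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):  # all tied: no rank information
            continue
        try:
            h, p = stats.kruskal(col[g0], col[g1])
        except ValueError:
            continue
        if not np.isfinite(h):
            continue
        stats_out[j], p_out[j] = h, p
    return stats_out, p_out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class FeatureSelectionResult:
    """Per-feature statistics and the overlap-selected index set."""

    lrt_statistic: np.ndarray
    lrt_p: np.ndarray
    kw_statistic: np.ndarray
    kw_p: np.ndarray
    kw_q: np.ndarray
    multivariate_significant: np.ndarray  # LRT p < alpha
    univariate_significant: np.ndarray  # BH q < alpha
    selected: np.ndarray  # intersection
    alpha: float

    def to_dataframe(self, mz: np.ndarray | None = None) -> pd.DataFrame:
        n = self.lrt_p.size
        df = pd.DataFrame({
            "feature": np.arange(n),
            "lrt_statistic": self.lrt_statistic, "lrt_p": self.lrt_p,
            "kw_statistic": self.kw_statistic, "kw_p": self.kw_p, "kw_q": self.kw_q,
            "multivariate_significant": np.isin(np.arange(n), self.multivariate_significant),
            "univariate_significant": np.isin(np.arange(n), self.univariate_significant),
            "selected": np.isin(np.arange(n), self.selected),
        })
        if mz is not None:
            df.insert(1, "mz", np.asarray(mz))
        return df


def select_features(table: CoreFeatureTable, alpha: float = 0.05) -> FeatureSelectionResult:
    """Run both screens and intersect the significant sets."""
    w = sample_weights(table.y)
    lrt_stat, lrt_p = lrt_per_feature(table.X, table.y, w)
    kw_stat, kw_p = kruskal_wallis_per_feature(table.X, table.y)
    kw_q = bh_adjust(kw_p)
    multi = np.flatnonzero(lrt_p < alpha)
    uni = np.flatnonzero(kw_q < alpha)
    selected = np.intersect1d(multi, uni)
    return FeatureSelectionResult(lrt_stat, lrt_p, kw_stat, kw_p, kw_q, multi, uni,
                                  selected, alpha)


@dataclass
class SelectionRefitResult:
    selection: FeatureSelectionResult
    cv_full: CVResult
    cv_reduced: CVResult


def select_and_refit(table: CoreFeatureTable, cv_seed: int = 0, alpha: float = 0.05,
                     n_splits: int = 10, regularization_strength: float = 1e-2,
                     folds: np.ndarray | None = None) -> SelectionRefitResult:
    """Select features, then cross-validate full and reduced models on the
    same folds so their metrics and ROC curves are directly comparable."""
    if folds is None:
        folds = slide_aware_stratified_folds(table.y, table.slide_ids, n_splits, cv_seed)
    selection = select_features(table, alpha)
    if selection.selected.size == 0:
        raise ValidationError(
            f"no features significant in both screens at alpha={alpha}; "
            "consider relaxing alpha")
    cv_full = cross_validate(table, folds=folds,
                             regularization_strength=regularization_strength)
    cv_reduced = cross_validate(table.subset_features(selection.selected), folds=folds,
                                regularization_strength=regularization_strength)
    return SelectionRefitResult(selection, cv_full, cv_reduced)
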