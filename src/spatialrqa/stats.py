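"""Cohort comparison statistics for SHRQA feature matrices.

The question the machinery answers: are two groups of patches (e.g. real
normal tissue vs. its synthetic counterpart) statistically indistinguishable
in their spatial-recurrence profile?

* :func:`lasso_select` — cross-validated logistic LASSO picking the features
  that carry the phenotype contrast;
* :func:`hotelling_t2` — two-sample Hotelling T² (the multivariate two-sample
  t-test) with the classical F approximation;
* :func:`pca_summary` / :func:`radar_profile` — standardized PCA and
  per-group mean ± CI profiles on the leading components, ready for radar
  plotting;
* :func:`qc_pass_rate` / :func:`classification_accuracy` — the small summary
  computations for pathologist QC tables and classifier tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SelectionResult",
    "GroupComparisonResult",
    "PCASummary",
    "lasso_select",
    "hotelling_t2",
    "pca_summary",
    "radar_profile",
    "qc_pass_rate",
    "load_qc_table",
    "classification_accuracy",
    "LassoFeatureSelector",
    "PCAProfile",
]


@dataclass
class SelectionResult:
    """Outcome of cross-validated LASSO feature selection."""

    selected_indices: list[int]
    lambda_used: float
    n_selected: int
    seed: int


@dataclass
class GroupComparisonResult:
    """Two-sample Hotelling T² with its F approximation."""

    t_squared: float
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    n1: int
    n2: int
    p_dims: int

    def as_dict(self) -> dict:
        return {
            "t_squared": self.t_squared,
            "f_statistic": self.f_statistic,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
            "n1": self.n1,
            "n2": self.n2,
            "p_dims": self.p_dims,
        }


@dataclass
class PCASummary:
    """Standardized-PCA decomposition of a feature matrix."""

    components: np.ndarray  # (n_components, n_features) loadings
    explained_variance_ratio: np.ndarray
    explained_variance: np.ndarray
    scores: np.ndarray  # (n_rows, n_components)
    n_components: int


# ---------------------------------------------------------------------------
# LASSO selection


class LassoFeatureSelector(SelectorMixin, BaseEstimator):
    """Logistic-LASSO feature selection with CV-minimum lambda.

    Columns are z-scored, constant columns dropped (with a warning), and an
    L1-penalized logistic regression is fit over a log-spaced penalty grid;
    the penalty minimizing mean cross-validated log-loss is kept and features
    with nonzero coefficients are selected.  Deterministic given ``seed``.

    Parameters
    ----------
    n_folds : int, default 10
        Stratified CV folds.
    seed : int, default 0
        Controls fold shuffling (the solver itself is deterministic).
    n_lambdas : int, default 25
        Size of the log-spaced penalty grid.
    Cs : array-like or None
        Explicit inverse-penalty grid overriding ``n_lambdas`` (a single tiny
        value forces full shrinkage, i.e. zero selected features).
    """

    def __init__(
        self, n_folds: int = 10, seed: int = 0, n_lambdas: int = 25, Cs=None
    ):
        self.n_folds = n_folds
        self.seed = seed
        self.n_lambdas = n_lambdas
        self.Cs = Cs

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(np.unique(y)) != 2:
            raise ValueError("lasso selection requires exactly two groups")
        if X.shape[0] < 2 * self.n_folds:
            raise ValueError(
                f"too few rows ({X.shape[0]}) for {self.n_folds}-fold CV; "
                "need at least 2 rows per fold"
            )
        self.n_features_in_ = X.shape[1]
        # ptp, not std: column-wise std of an exactly constant column can
        # round to ~1e-15 instead of 0
        usable = np.ptp(X, axis=0) > 0
        if not usable.all():
            warnings.warn(
                f"dropping {int((~usable).sum())} constant feature(s) before LASSO",
                stacklevel=2,
            )
        Xs = StandardScaler().fit_transform(X[:, usable])
        cv = StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        grid = self.Cs if self.Cs is not None else np.logspace(-3, 2, self.n_lambdas)
        model = LogisticRegressionCV(
            Cs=grid,
            cv=cv,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=2000,
            random_state=self.seed,
        )
        model.fit(Xs, y)
        coef = np.zeros(self.n_features_in_)
        coef[usable] = model.coef_.ravel()
        self.coef_ = coef
        self.C_ = float(model.C_[0])
        self.lambda_used_ = 1.0 / self.C_
        self.support_ = np.abs(coef) > 1e-10
        self.selected_indices_ = np.flatnonzero(self.support_).tolist()
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_

    def result(self) -> SelectionResult:
        return SelectionResult(
            selected_indices=self.selected_indices_,
            lambda_used=self.lambda_used_,
            n_selected=len(self.selected_indices_),
            seed=self.seed,
        )


def lasso_select(X, labels, n_folds: int = 10, seed: int = 0) -> SelectionResult:
    """Functional wrapper around :class:`LassoFeatureSelector`."""
    return LassoFeatureSelector(n_folds=n_folds, seed=seed).fit(X, labels).result()


# ---------------------------------------------------------------------------
# Hotelling's T-squared


def hotelling_t2(A, B, shrinkage: float = 0.0) -> GroupComparisonResult:
    """Two-sample Hotelling T² test of equal mean vectors.

    ``T² = (n1 n2 / (n1+n2)) d' S⁻¹ d`` with pooled covariance ``S`` and mean
    difference ``d``; ``F = T² (n1+n2-p-1) / (p (n1+n2-2))`` follows an
    F(p, n1+n2-p-1) distribution under multivariate normality.

    Parameters
    ----------
    A, B : (n, p) arrays
        Feature rows of the two groups.
    shrinkage : float in [0, 1)
        Optional ridge toward the diagonal of S, ``(1-a) S + a diag(S)``, for
        ill-conditioned pooled covariances; 0 (default) is the plain test.
    """
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the feature dimension")
    n1, n2, p = A.shape[0], B.shape[0], A.shape[1]
    if n1 + n2 - 2 <= p:
        raise ValueError(
            f"n1+n2-2 = {n1 + n2 - 2} must exceed p = {p}; reduce the feature "
            "space first (selection, PCA, or covariance shrinkage)"
        )
    d = A.mean(axis=0) - B.mean(axis=0)
    S = ((n1 - 1) * np.cov(A, rowvar=False) + (n2 - 1) * np.cov(B, rowvar=False)) / (
        n1 + n2 - 2
    )
    S = np.atleast_2d(S)
    if shrinkage > 0:
        S = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    try:
        solved = np.linalg.solve(S, d)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; drop collinear features or use "
            "shrinkage / PCA reduction"
        ) from exc
    t2 = float(n1 * n2 / (n1 + n2) * d @ solved)
    df1, df2 = p, n1 + n2 - p - 1
    f_stat = t2 * df2 / (p * (n1 + n2 - 2))
    p_value = float(sps.f.sf(f_stat, df1, df2))
    return GroupComparisonResult(
        t_squared=t2,
        f_statistic=float(f_stat),
        df1=df1,
        df2=df2,
        p_value=p_value,
        n1=n1,
        n2=n2,
        p_dims=p,
    )


# ---------------------------------------------------------------------------
# PCA profiles


class PCAProfile(BaseEstimator, TransformerMixin):
    """Standardized PCA (z-score then PCA) exposing the usual fitted attributes.

    Features are z-scored first because the recurrence features mix scales
    (probabilities, counts, entropies).
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        self.n_features_in_ = X.shape[1]
        self.scaler_ = StandardScaler()
        Xs = self.scaler_.fit_transform(X)
        max_rank = min(X.shape[0] - 1, X.shape[1])
        k = min(self.n_components, max_rank)
        if k < self.n_components:
            warnings.warn(
                f"n_components truncated from {self.n_components} to rank {k}",
                stacklevel=2,
            )
        self.pca_ = PCA(n_components=k, svd_solver="full")
        self.scores_ = self.pca_.fit_transform(Xs)
        self.components_ = self.pca_.components_
        self.explained_variance_ = self.pca_.explained_variance_
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        self.n_components_ = k
        return self

    def transform(self, X) -> np.ndarray:
        return self.pca_.transform(self.scaler_.transform(np.asarray(X, dtype=np.float64)))

    def summary(self) -> PCASummary:
        return PCASummary(
            components=self.components_,
            explained_variance_ratio=self.explained_variance_ratio_,
            explained_variance=self.explained_variance_,
            scores=self.scores_,
            n_components=self.n_components_,
        )


def pca_summary(X, n_components: int = 5) -> PCASummary:
    """Functional wrapper around :class:`PCAProfile`."""
    return PCAProfile(n_components=n_components).fit(X).summary()


def radar_profile(
    pca: PCASummary, labels, n_pcs: int = 5, ci: float = 0.95
) -> pd.DataFrame:
    """Per-group mean and t-based confidence band on each leading component.

    Returns a table with columns ``group, component, mean, ci_lo, ci_hi, n``
    (the plot-ready form of a radar profile); groups with fewer than 3 rows
    get NaN confidence bounds.
    """
    if n_pcs > pca.n_components:
        raise ValueError(f"n_pcs={n_pcs} exceeds available components {pca.n_components}")
    labels = np.asarray(labels)
    if len(labels) != pca.scores.shape[0]:
        raise ValueError("labels must align with PCA score rows")
    rows = []
    for group in pd.unique(labels):
        scores = pca.scores[labels == group, :n_pcs]
        n = scores.shape[0]
        means = scores.mean(axis=0)
        if n >= 3:
            half = (
                sps.t.ppf((1 + ci) / 2, df=n - 1)
                * scores.std(axis=0, ddof=1)
                / np.sqrt(n)
            )
        else:
            half = np.full(n_pcs, np.nan)
        for k in range(n_pcs):
            rows.append(
                {
                    "group": group,
                    "component": k + 1,
                    "mean": means[k],
                    "ci_lo": means[k] - half[k],
                    "ci_hi": means[k] + half[k],
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QC-table and accuracy arithmetic


def load_qc_table(path: str | Path) -> pd.DataFrame:
    """Read a pathologist QC table (rows = tissues, cells = P/F) from CSV."""
    df = pd.read_csv(path, index_col=0)
    return df


def qc_pass_rate(table: pd.DataFrame) -> float:
    """Fraction of P cells in a P/F quality-control table."""
    values = table.to_numpy(dtype=object)
    for (i, j), cell in np.ndenumerate(values):
        v = str(cell).strip().upper()
        if v not in ("P", "F"):
            raise ValueError(
                f"malformed QC cell {cell!r} at row {table.index[i]!r}, "
                f"column {table.columns[j]!r} (expected P or F)"
            )
        values[i, j] = v
    return float((values == "P").mean())


def classification_accuracy(n_correct: int, n_total: int) -> float:
    """Percent accuracy ``100 * n_correct / n_total``."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must lie in [0, n_total]")
    return 100.0 * n_correct / n_total
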