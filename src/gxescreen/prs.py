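"""Polygenic-score aggregation across p-value thresholds (PRS-PCA).

Per-threshold polygenic scores (typically 10 GWAS p-value thresholds,
5e-8 ... 1) are highly correlated but differ in scale by orders of
magnitude.  ``PrsPca`` standardises each threshold column, takes the first
principal component of the resulting correlation matrix, aligns its sign
with the mean standardised score (so higher always means higher genetic
burden, without peeking at any outcome), and re-standardises the component
to mean 0 / SD 1 over the analysis sample.  The aggregated score is then
dichotomised at the 75th percentile into high- vs low-risk groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["PrsPca", "PrsResult", "prs_pca", "dichotomize_prs", "read_prsice_all_score"]


class PrsPca(TransformerMixin, BaseEstimator):
    """First principal component of standardised per-threshold scores.

    Parameters
    ----------
    high_quantile : float, default 0.75
        Quantile at which :meth:`fit_result` dichotomises the score.

    Attributes
    ----------
    loadings_ : ndarray of shape (n_thresholds,)
        PC1 loadings on the standardised columns, sign-aligned so the
        component correlates positively with the row-wise mean of the
        standardised columns.
    pc1_variance_fraction_ : float
        Share of total variance carried by PC1.
    eigenvalues_ : ndarray
        Correlation-matrix eigenvalues, descending.
    """

    def __init__(self, high_quantile: float = 0.75):
        self.high_quantile = high_quantile

    def _coerce(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            names = [f"column_{j}" for j in range(arr.shape[1])] if arr.ndim == 2 else []
        if arr.ndim != 2:
            raise ValueError("score matrix must be 2-dimensional")
        if np.isnan(arr).any():
            raise ValueError(
                "score matrix contains missing values; exclude incomplete rows upstream"
            )
        return arr, names

    def fit(self, X, y=None) -> "PrsPca":
        arr, names = self._coerce(X)
        n, k = arr.shape
        if n <= k:
            raise ValueError(f"need more rows than threshold columns (n={n}, k={k})")
        mean = arr.mean(axis=0)
        scale = arr.std(axis=0, ddof=1)
        zero = np.flatnonzero(scale == 0)
        if zero.size:
            raise ValueError(f"threshold column {names[zero[0]]} has zero variance")
        Z = (arr - mean) / scale
        R = (Z.T @ Z) / (n - 1)
        eigvals, eigvecs = np.linalg.eigh(R)
        v = eigvecs[:, -1]
        s = Z @ v
        # sign alignment: PC1 must correlate positively with the mean
        # standardised score; ties broken toward positive loading sum
        m = Z.mean(axis=1)
        cov = float(np.dot(s - s.mean(), m - m.mean()))
        if cov < 0 or (cov == 0 and v.sum() < 0):
            v = -v
            s = -s
        self.n_features_in_ = k
        self.feature_names_in_ = np.asarray(names)
        self.mean_ = mean
        self.scale_ = scale
        self.loadings_ = v
        self.eigenvalues_ = eigvals[::-1].copy()
        self.pc1_variance_fraction_ = float(eigvals[-1] / eigvals.sum())
        self.score_center_ = float(s.mean())
        self.score_scale_ = float(s.std(ddof=1))
        if self.score_scale_ == 0:
            raise ValueError("PC1 scores are constant; cannot standardise")
        return self

    def transform(self, X) -> np.ndarray:
        arr, _ = self._coerce(X)
        if arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} threshold columns, got {arr.shape[1]}"
            )
        Z = (arr - self.mean_) / self.scale_
        s = Z @ self.loadings_
        return (s - self.score_center_) / self.score_scale_

    def fit_result(self, X) -> "PrsResult":
        score = self.fit(X).transform(X)
        return PrsResult(
            score=score,
            high=dichotomize_prs(score, self.high_quantile),
            loadings=self.loadings_.copy(),
            pc1_variance_fraction=self.pc1_variance_fraction_,
        )


@dataclass(frozen=True)
class PrsResult:
    """Aggregated polygenic score: standardised PC1 plus the high/low split."""

    score: np.ndarray
    high: np.ndarray
    loadings: np.ndarray
    pc1_variance_fraction: float


def prs_pca(score_matrix, high_quantile: float = 0.75) -> PrsResult:
    """Aggregate an n x k per-threshold score matrix into one standardised PRS."""
    return PrsPca(high_quantile=high_quantile).fit_result(score_matrix)


def dichotomize_prs(score, quantile: float = 0.75) -> np.ndarray:
    """High-risk indicator: strictly above the empirical ``quantile``.

    The quantile uses linear interpolation (numpy default); ties at the
    threshold fall into the low group, so a constant vector has no
    high-risk rows.  Deterministic and seed-free.
    """
    arr = np.asarray(score, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot dichotomize an empty score vector")
    threshold = np.quantile(arr, quantile)
    return (arr > threshold).astype(np.int64)


def read_prsice_all_score(path: str) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Read a PRSice-style "all score" table (FID/IID + one column per threshold).

    Returns participant ids, the numeric score matrix, and the threshold
    labels parsed from the column headers (``Pt_0.001`` -> ``"0.001"``).
    A generic TSV with one id column followed by score columns also works.
    """
    table = pd.read_csv(path, sep=None, engine="python")
    id_cols = [c for c in table.columns if str(c).upper() in ("FID", "IID")]
    if id_cols:
        ids = table[id_cols[-1]].astype(str)
        scores = table.drop(columns=id_cols)
    else:
        ids = table.iloc[:, 0].astype(str)
        scores = table.iloc[:, 1:]
    scores = scores.apply(pd.to_numeric)
    labels = [str(c)[3:] if str(c).startswith("Pt_") else str(c) for c in scores.columns]
    return ids, scores, labels
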