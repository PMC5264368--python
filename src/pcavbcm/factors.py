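"""Correlation-matrix PCA with varimax rotation and regression factor scores.

This is the behavioural half of the lesion-mapping method: a battery of
percent-correct test scores is decomposed into a small number of orthogonal
components.  Components are extracted from the Pearson correlation matrix,
retained by the Kaiser criterion (eigenvalue strictly greater than 1), rotated
with (Kaiser-row-normalised) varimax for interpretability, and each patient is
assigned factor scores by the regression (Thomson) method, ``R^{-1} L``.  Under
principal-component extraction and an orthogonal rotation, regression scores
have exactly zero mean, unit variance and zero cross-correlation, which is the
property the voxelwise analysis relies on (orthogonal behavioural regressors).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def standardize(X: np.ndarray, columns: Sequence[str] | None = None) -> np.ndarray:
    """Column-wise z-transform with the sample (n-1) standard deviation.

    Raises ``ValueError`` naming the offending measure if a column is constant.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [columns[j] if columns is not None else f"column {j}" for j in bad]
        raise ValueError(f"constant column(s) cannot be standardized: {names}")
    return (X - mean) / sd


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation of a loading matrix.

    Maximises the varimax criterion (the sum over factors of the variance of
    squared loadings, computed on row-normalised loadings when
    ``kaiser_normalize`` is set, which is the SPSS default).  Returns
    ``(rotated_loadings, rotation)`` with ``rotated = loadings @ rotation`` and
    ``rotation`` orthogonal.  A single-factor matrix is returned unchanged.
    """
    L = np.array(loadings, dtype=float)
    if L.ndim != 2:
        raise ValueError("loadings must be 2-D")
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    if kaiser_normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        Lw = L / h[:, None]
    else:
        Lw = L
    R = np.eye(k)
    objective = 0.0
    converged = False
    for _ in range(max_iter):
        Lr = Lw @ R
        # gradient step via SVD (Lawley-Maxwell form of the varimax update)
        G = Lw.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(G)
        R = u @ vt
        new_objective = s.sum()
        if new_objective <= objective * (1.0 + tol):
            converged = True
            break
        objective = new_objective
    if not converged:
        raise RuntimeError(
            f"varimax did not converge in {max_iter} iterations "
            f"(last criterion increase {new_objective - objective:.3e})"
        )
    return L @ R, R


def varimax_criterion(loadings: np.ndarray, kaiser_normalize: bool = True) -> float:
    """Value of the varimax simplicity criterion for a loading matrix."""
    L = np.array(loadings, dtype=float)
    if kaiser_normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    sq = L**2
    return float((sq.var(axis=0)).sum())


def factor_scores(
    z_matrix: np.ndarray, correlation: np.ndarray, rotated_loadings: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Regression (Thomson) factor scores: ``W = R^{-1} L``, ``S = Z W``.

    Falls back to the Moore-Penrose pseudo-inverse when the correlation matrix
    is numerically singular.
    """
    R = np.asarray(correlation, dtype=float)
    L = np.asarray(rotated_loadings, dtype=float)
    try:
        W = np.linalg.solve(R, L)
    except np.linalg.LinAlgError:
        W = np.linalg.pinv(R) @ L
    return np.asarray(z_matrix, float) @ W, W


class VarimaxPCA(BaseEstimator, TransformerMixin):
    """PCA of the correlation matrix with Kaiser retention and varimax rotation.

    Parameters
    ----------
    n_components :
        Number of components to retain.  ``None`` (default) applies the Kaiser
        criterion: retain components with eigenvalue strictly above
        ``eigenvalue_threshold``.
    eigenvalue_threshold :
        Retention cut-off on correlation-matrix eigenvalues (default 1.0).
    rotate :
        Apply varimax rotation when two or more components are retained.
    kaiser_normalize :
        Row-normalise loadings during rotation (SPSS default).
    sort_by_variance :
        Order rotated factors by descending sum of squared loadings and flip
        each factor's sign so its dominant measure loads positively.  This
        makes the solution deterministic across linear-algebra backends.

    Attributes
    ----------
    feature_names_in_ : measure names when fitted on a DataFrame.
    eigenvalues_ : all m correlation-matrix eigenvalues, descending.
    n_components_ : number of retained components k.
    loadings_ : unrotated m x k loadings (eigenvector * sqrt(eigenvalue)).
    rotation_ : k x k orthogonal rotation matrix.
    rotated_loadings_ : m x k varimax-rotated loadings.
    variance_fraction_ : per-component eigenvalue / m for the retained set.
    total_variance_fraction_ : retained-variance fraction, rotation-invariant.
    score_coefficients_ : m x k regression score coefficients.
    scores_ : n x k factor scores of the training sample (mean 0, variance 1).
    """

    def __init__(
        self,
        n_components: int | None = None,
        eigenvalue_threshold: float = 1.0,
        rotate: bool = True,
        kaiser_normalize: bool = True,
        tol: float = 1e-6,
        max_iter: int = 1000,
        sort_by_variance: bool = True,
    ):
        self.n_components = n_components
        self.eigenvalue_threshold = eigenvalue_threshold
        self.rotate = rotate
        self.kaiser_normalize = kaiser_normalize
        self.tol = tol
        self.max_iter = max_iter
        self.sort_by_variance = sort_by_variance

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray(
                [f"x{j}" for j in range(X.shape[1])], dtype=object
            )
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need a 2-D matrix with at least 3 rows")
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in input matrix")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        names = list(self.feature_names_in_)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        Z = standardize(X, names)
        R = np.corrcoef(X, rowvar=False)
        if not np.isfinite(R).all():
            raise ValueError("non-finite correlation matrix")
        eigvals, eigvecs = np.linalg.eigh(R)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        self.correlation_ = R
        self.eigenvalues_ = eigvals
        if self.n_components is None:
            k = int((eigvals > self.eigenvalue_threshold).sum())
            if k == 0:
                raise ValueError(
                    "no component exceeds the retention threshold "
                    f"{self.eigenvalue_threshold}"
                )
        else:
            k = int(self.n_components)
        self.n_components_ = k
        self.loadings_ = eigvecs[:, :k] * np.sqrt(np.clip(eigvals[:k], 0, None))
        self.variance_fraction_ = eigvals[:k] / R.shape[0]
        self.total_variance_fraction_ = float(self.variance_fraction_.sum())
        if self.rotate and k >= 2:
            rotated, rotation = varimax(
                self.loadings_, self.kaiser_normalize, self.tol, self.max_iter
            )
        else:
            rotated, rotation = self.loadings_.copy(), np.eye(k)
        self.rotated_loadings_ = rotated
        self.rotation_ = rotation
        if self.sort_by_variance:
            align_signs(self)
        self.score_coefficients_ = factor_scores(
            Z, R, self.rotated_loadings_
        )[1]
        self.scores_ = Z @ self.score_coefficients_
        return self

    def transform(self, X):
        """Factor scores for new rows, standardised by the training sample."""
        check_is_fitted(self, "score_coefficients_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        Z = (np.asarray(X, float) - self.mean_) / self.scale_
        return Z @ self.score_coefficients_

    def communalities(self, rotated: bool = True) -> np.ndarray:
        check_is_fitted(self, "rotated_loadings_")
        L = self.rotated_loadings_ if rotated else self.loadings_
        return (L**2).sum(axis=1)

    def loadings_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "rotated_loadings_")
        cols = [f"F{j + 1}" for j in range(self.n_components_)]
        return pd.DataFrame(
            self.rotated_loadings_, index=self.feature_names_in_, columns=cols
        )

    def scores_frame(self, index=None) -> pd.DataFrame:
        check_is_fitted(self, "scores_")
        cols = [f"F{j + 1}" for j in range(self.n_components_)]
        return pd.DataFrame(self.scores_, index=index, columns=cols)


def align_signs(model: VarimaxPCA) -> VarimaxPCA:
    """Canonicalise a fitted model in place: order rotated factors by
    descending explained (sum-of-squares) loading and flip signs so each
    factor's largest-magnitude loading is positive.  Idempotent."""
    check_is_fitted(model, "rotated_loadings_")
    L = model.rotated_loadings_
    order = np.argsort(-(L**2).sum(axis=0), kind="stable")
    L = L[:, order]
    dominant = np.abs(L).argmax(axis=0)
    signs = np.sign(L[dominant, np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    model.rotated_loadings_ = L * signs
    model.rotation_ = model.rotation_[:, order] * signs
    if hasattr(model, "score_coefficients_"):
        model.score_coefficients_ = model.score_coefficients_[:, order] * signs
        model.scores_ = model.scores_[:, order] * signs
    return model


def fit_pca(score_matrix, **kwargs) -> VarimaxPCA:
    """Fit the standard battery decomposition on a patients x measures table."""
    return VarimaxPCA(**kwargs).fit(score_matrix)
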