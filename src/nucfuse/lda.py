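"""Supervised linear dimension reduction by discriminant analysis.

Maximizes the ratio of between-class to within-class scatter,

    J(W) = |Wᵀ S_B W| / |Wᵀ S_W W|,

whose optimal columns solve the generalized eigenproblem
S_B w = λ S_W w.  At most C-1 eigenvalues are nonzero for C classes, so
the projection has at most C-1 components.  S_W is singular whenever the
feature dimension exceeds the sample count (routine here: 630D fused
vectors vs. a few hundred proteins), so a small ridge proportional to
trace(S_W)/d is added by default before solving; the ridge actually used
is recorded on the fitted model.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

RidgePolicy = Literal["auto", "off"]

_RIDGE_SCALE = 1e-6


def scatter_matrices(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray], np.ndarray]:
    """Within-class scatter S_W, between-class scatter S_B, class means, total mean.

    S_W = Σ_c Σ_{x in c} (x-μ_c)(x-μ_c)ᵀ ;  S_B = Σ_c N_c (μ_c-μ)(μ_c-μ)ᵀ,
    with μ the sample-size-weighted mean of the class means.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = X.shape[1]
    classes = np.unique(y)
    mu = X.mean(axis=0)
    S_W = np.zeros((d, d))
    S_B = np.zeros((d, d))
    class_means: dict[int, np.ndarray] = {}
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        class_means[int(c)] = mc
        Dc = Xc - mc
        S_W += Dc.T @ Dc
        dm = (mc - mu)[:, None]
        S_B += Xc.shape[0] * (dm @ dm.T)
    return S_W, S_B, class_means, mu


class LinearDiscriminantReducer(BaseEstimator, TransformerMixin):
    """Scatter-ratio discriminant projection onto at most C-1 components.

    Parameters
    ----------
    n_components : int or "max"
        Requested projection dimension; capped at min(C-1, rank(S_B)).
    ridge_policy : {"auto", "off"}
        "auto" adds ridge = 1e-6 * trace(S_W)/d * I to S_W before solving,
        which regularizes the (typically singular) within-class scatter;
        "off" raises on a singular S_W.

    Attributes
    ----------
    components_ : (d, m) projection matrix, columns ordered by descending
        generalized eigenvalue, sign fixed so the largest-magnitude entry
        of each column is positive.
    eigenvalues_ : (m,) the corresponding generalized eigenvalues.
    class_means_ : dict class -> mean vector.
    mean_ : total mean vector.
    ridge_ : the scalar ridge actually added to S_W.
    """

    def __init__(
        self,
        n_components: int | str = "max",
        ridge_policy: RidgePolicy = "auto",
    ):
        self.n_components = n_components
        self.ridge_policy = ridge_policy

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearDiscriminantReducer":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        N, d = X.shape
        classes = np.unique(y)
        C = classes.size
        if C < 2:
            raise ValueError(f"need at least 2 classes, got {C}")
        if N < C:
            raise ValueError(f"need at least as many samples as classes ({N} < {C})")
        singletons = [int(c) for c in classes if np.sum(y == c) < 2]
        if singletons:
            warnings.warn(
                f"classes {singletons} have a single sample and contribute "
                "zero within-class scatter",
                stacklevel=2,
            )

        S_W, S_B, class_means, mu = scatter_matrices(X, y)

        if self.ridge_policy == "auto":
            ridge = _RIDGE_SCALE * np.trace(S_W) / d
            # an all-identical-within-class degenerate input has trace 0
            if ridge <= 0.0:
                ridge = _RIDGE_SCALE
        elif self.ridge_policy == "off":
            ridge = 0.0
            if np.linalg.matrix_rank(S_W) < d:
                raise np.linalg.LinAlgError(
                    "within-class scatter S_W is singular; the generalized "
                    "eigenproblem S_B w = λ S_W w requires nonsingular S_W "
                    "(enable ridge_policy='auto')"
                )
        else:
            raise ValueError(f"unknown ridge_policy {self.ridge_policy!r}")

        Sw_reg = S_W + ridge * np.eye(d)
        # symmetric-definite solver: whitens by Sw_reg internally
        eigvals, eigvecs = scipy.linalg.eigh(S_B, Sw_reg)
        order = np.argsort(eigvals)[::-1]
        eigvals = eigvals[order]
        eigvecs = eigvecs[:, order]

        rank_b = int(np.linalg.matrix_rank(S_B))
        m_cap = min(C - 1, rank_b)
        if self.n_components == "max":
            m = m_cap
        else:
            m = min(int(self.n_components), m_cap)
        if m < 1:
            raise ValueError("between-class scatter has rank 0; classes coincide")

        W = eigvecs[:, :m].copy()
        lam = np.maximum(eigvals[:m], 0.0)
        # deterministic sign: largest-magnitude entry of each column positive
        flip = W[np.argmax(np.abs(W), axis=0), np.arange(m)] < 0
        W[:, flip] *= -1.0

        self.components_ = W
        self.eigenvalues_ = lam
        self.class_means_ = class_means
        self.mean_ = mu
        self.ridge_ = float(ridge)
        self.n_features_in_ = d
        self.classes_ = classes
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project rows of X: Y = X W (equivalently y = Wᵀ x per sample)."""
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return X @ self.components_

    @property
    def m(self) -> int:
        check_is_fitted(self, "components_")
        return int(self.components_.shape[1])


def lda_fit(
    X: np.ndarray,
    y: np.ndarray,
    m: int | str = "max",
    ridge_policy: RidgePolicy = "auto",
) -> LinearDiscriminantReducer:
    """Fit a discriminant projection (thin wrapper over the estimator)."""
    return LinearDiscriminantReducer(n_components=m, ridge_policy=ridge_policy).fit(X, y)


def lda_transform(model: LinearDiscriminantReducer, X: np.ndarray) -> np.ndarray:
    """Project X with a fitted model."""
    return model.transform(X)


def rayleigh_ratios(model: LinearDiscriminantReducer, X, y) -> np.ndarray:
    """Per-component generalized Rayleigh ratios wᵀS_B w / wᵀ(S_W+ridge I)w."""
    S_W, S_B, _, _ = scatter_matrices(np.asarray(X, float), np.asarray(y))
    Sw_reg = S_W + model.ridge_ * np.eye(S_W.shape[0])
    W = model.components_
    num = np.einsum("di,de,ei->i", W, S_B, W)
    den = np.einsum("di,de,ei->i", W, Sw_reg, W)
    return num / den
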