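"""Cosine-similarity k-nearest-neighbour classification.

Two estimators:

* :class:`CosineKNN` — plain KNN on any feature table, ranking neighbours
  by cosine similarity cos(u, v) = u·v / (‖u‖‖v‖).
* :class:`BalancedFusionKNN` — the full fused-representation classifier.
  Its input X is the unweighted concatenation [A | B] of a composition-type
  block and a compressed-PSSM block; training vectors are fused with their
  own class's balance factor, and a query is compared to a training
  neighbour of class c with both vectors fused by r_c (candidate-class
  weighting), which keeps prediction label-free.  Optional per-feature
  z-scoring of the raw blocks and a discriminant projection are fitted on
  the training data only.

Vote ties are broken by the larger summed similarity within the tied
classes, then by the smaller class code; exact similarity ties at the
k-boundary go to the smaller training index.  All rules are deterministic.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .fusion import BalanceVector
from .lda import LinearDiscriminantReducer


def cosine_similarity_matrix(Q: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between rows of Q and rows of T."""
    Qn = np.linalg.norm(Q, axis=1, keepdims=True)
    Tn = np.linalg.norm(T, axis=1, keepdims=True)
    if np.any(Qn == 0.0):
        raise ValueError("zero-norm query vector: cosine similarity undefined")
    if np.any(Tn == 0.0):
        raise ValueError("zero-norm training vector: cosine similarity undefined")
    return (Q / Qn) @ (T / Tn).T


def _vote(sims: np.ndarray, train_y: np.ndarray, k: int) -> np.ndarray:
    """Majority vote over the k most similar training samples per query row."""
    n_q, n_t = sims.shape
    out = np.empty(n_q, dtype=train_y.dtype)
    idx = np.arange(n_t)
    for qi in range(n_q):
        s = sims[qi]
        # descending similarity; exact ties -> smaller training index
        order = np.lexsort((idx, -s))[:k]
        neigh_y = train_y[order]
        neigh_s = s[order]
        classes, counts = np.unique(neigh_y, return_counts=True)
        top = counts.max()
        tied = classes[counts == top]
        if tied.size > 1:
            sums = np.array([neigh_s[neigh_y == c].sum() for c in tied])
            best = sums.max()
            # larger summed similarity, then smaller class code
            tied = tied[sums >= best - 1e-12]
        out[qi] = tied.min()
    return out


class CosineKNN(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbour classifier under cosine similarity."""

    def __init__(self, k: int = 1):
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CosineKNN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds training size {X.shape[0]}")
        norms = np.linalg.norm(X, axis=1)
        zero = np.flatnonzero(norms == 0.0)
        if zero.size:
            raise ValueError(
                f"zero-norm training vector(s) at row(s) {zero.tolist()}: "
                "cosine similarity undefined"
            )
        self.train_X_ = X
        self.train_y_ = y
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def similarity(self, Q: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "train_X_")
        Q = np.asarray(Q, dtype=float)
        if Q.ndim == 1:
            Q = Q[None, :]
        if Q.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {Q.shape[1]} features, model expects "
                f"{self.n_features_in_}"
            )
        return cosine_similarity_matrix(Q, self.train_X_)

    def predict(self, Q: np.ndarray) -> np.ndarray:
        return _vote(self.similarity(Q), self.train_y_, self.k)

    def kneighbors(self, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Indices and similarities of the k nearest training samples."""
        sims = self.similarity(Q)
        idx = np.arange(sims.shape[1])
        order = np.vstack([np.lexsort((idx, -s))[: self.k] for s in sims])
        return order, np.take_along_axis(sims, order, axis=1)


class BalancedFusionKNN(BaseEstimator, ClassifierMixin):
    """Cosine-KNN on per-class balance-factor fused [A | B] blocks.

    Parameters
    ----------
    split : int
        Number of leading columns of X forming block A; the rest is block B.
    R : BalanceVector, array of shape (n_classes,), or None
        Balance factors indexed by class code order; None means the
        equal-importance baseline r_i = 0.5.
    k : int
        Neighbourhood size.
    use_lda : bool
        Fit a discriminant projection on the true-label-fused training data
        and compare in the projected space.
    n_components : int or "max"
        Projection dimension when use_lda is set.
    zscore : bool
        Per-feature standardization of the raw blocks, fitted on training
        data only, applied before fusion.
    """

    def __init__(
        self,
        split: int,
        R: BalanceVector | np.ndarray | None = None,
        k: int = 1,
        use_lda: bool = False,
        n_components: int | str = "max",
        zscore: bool = False,
    ):
        self.split = split
        self.R = R
        self.k = k
        self.use_lda = use_lda
        self.n_components = n_components
        self.zscore = zscore

    def _r_array(self, n_classes: int) -> np.ndarray:
        if self.R is None:
            return np.full(n_classes, 0.5)
        r = self.R.r if isinstance(self.R, BalanceVector) else np.asarray(self.R, float)
        if r.size != n_classes:
            raise ValueError(
                f"balance vector has {r.size} factors for {n_classes} classes"
            )
        return r

    def _scale(self, X: np.ndarray) -> np.ndarray:
        if not self.zscore:
            return X
        return (X - self.mu_) / self.sd_

    def _fuse(self, X: np.ndarray, r: float | np.ndarray) -> np.ndarray:
        """Row-wise fusion [r*A, (1-r)*B]; r scalar or per-row."""
        A, B = X[:, : self.split], X[:, self.split :]
        r = np.asarray(r, dtype=float).reshape(-1, 1)
        return np.hstack([r * A, (1.0 - r) * B])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedFusionKNN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not (0 < self.split < X.shape[1]):
            raise ValueError(
                f"split={self.split} must cut X (width {X.shape[1]}) into two "
                "non-empty blocks"
            )
        if self.k < 1 or self.k > X.shape[0]:
            raise ValueError(f"k={self.k} invalid for {X.shape[0]} training samples")
        self.classes_ = np.unique(y)
        self.r_ = self._r_array(self.classes_.size)
        if self.zscore:
            self.mu_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.sd_ = np.where(sd == 0.0, 1.0, sd)
        Xs = self._scale(X)
        # class code -> position in classes_ for each training sample
        pos = np.searchsorted(self.classes_, y)
        fused = self._fuse(Xs, self.r_[pos])
        if self.use_lda:
            self.reducer_ = LinearDiscriminantReducer(
                n_components=self.n_components
            ).fit(fused, y)
            fused = self.reducer_.transform(fused)
        else:
            self.reducer_ = None
        norms = np.linalg.norm(fused, axis=1)
        if np.any(norms == 0.0):
            raise ValueError("zero-norm fused training vector")
        self.train_fused_ = fused
        self.train_y_ = y
        self.train_pos_ = pos
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, Q: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "train_fused_")
        Q = np.asarray(Q, dtype=float)
        if Q.ndim == 1:
            Q = Q[None, :]
        if Q.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {Q.shape[1]} features, model expects "
                f"{self.n_features_in_}"
            )
        Qs = self._scale(Q)
        n_q = Qs.shape[0]
        sims = np.empty((n_q, self.train_fused_.shape[0]))
        for ci in range(self.classes_.size):
            mask = self.train_pos_ == ci
            if not mask.any():
                continue
            Qc = self._fuse(Qs, float(self.r_[ci]))
            if self.reducer_ is not None:
                Qc = self.reducer_.transform(Qc)
            sims[:, mask] = cosine_similarity_matrix(Qc, self.train_fused_[mask])
        return _vote(sims, self.train_y_, self.k)


def knn_fit(X: np.ndarray, y: np.ndarray, k: int = 1) -> CosineKNN:
    """Fit a cosine-KNN model (thin wrapper over the estimator)."""
    return CosineKNN(k=k).fit(X, y)


def knn_predict(model: CosineKNN, Q: np.ndarray) -> np.ndarray:
    """Predict labels for queries with a fitted cosine-KNN model."""
    return model.predict(Q)
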