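"""Cross-validated evaluation: stratified K-fold, jackknife, and the
per-location metrics SE, SP, ACC and MCC.

Per location i the one-vs-rest confusion counts give

    SE(i)  = TP/(TP+FN)                 (identical to the per-class success
                                         rate T(i)/N(i) on pooled predictions)
    SP(i)  = TN/(TN+FP)
    ACC(i) = (TP+TN)/(TP+TN+FP+FN)
    MCC(i) = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 when its denominator vanishes.  The overall success
rate is Σ_i T(i) / Σ_i N(i).  K-fold partitions are stratified (per-class
fold counts differ by at most one) and deterministic per seed; the
jackknife (leave-one-out, the K = N special case) is deterministic
regardless of seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone

METRIC_COLUMNS = ["SE", "SP", "ACC", "MCC"]


@dataclass
class MetricsReport:
    """Per-class and overall evaluation results plus the config that made them."""

    per_class: pd.DataFrame
    overall_success_rate: float
    config: dict = field(default_factory=dict)
    per_repeat_overall: list[float] = field(default_factory=list)
    per_k_overall: dict[int, float] = field(default_factory=dict)
    per_k_repeat_overall: dict[int, list[float]] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            self.per_class.to_csv(fh, sep="\t", index_label="class")
            fh.write(f"# overall_success_rate\t{self.overall_success_rate!r}\n")
            for key, val in sorted(self.config.items()):
                fh.write(f"# {key}\t{val}\n")


def confusion_counts(true: np.ndarray, pred: np.ndarray, n: int) -> pd.DataFrame:
    """One-vs-rest TP/TN/FP/FN per class code 1..n."""
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.shape != pred.shape:
        raise ValueError("true and pred must have equal length")
    for name, arr in (("true", true), ("pred", pred)):
        bad = arr[(arr < 1) | (arr > n)]
        if bad.size:
            raise ValueError(f"{name} labels outside 1..{n}: {sorted(set(bad))}")
    rows = []
    for c in range(1, n + 1):
        tp = int(np.sum((true == c) & (pred == c)))
        fn = int(np.sum((true == c) & (pred != c)))
        fp = int(np.sum((true != c) & (pred == c)))
        tn = int(np.sum((true != c) & (pred != c)))
        rows.append((c, tp, tn, fp, fn))
    return pd.DataFrame(
        rows, columns=["class", "TP", "TN", "FP", "FN"]
    ).set_index("class")


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def compute_metrics(
    true: Sequence[int], pred: Sequence[int], n: int, config: dict | None = None
) -> MetricsReport:
    """SE/SP/ACC/MCC per class and the overall success rate."""
    counts = confusion_counts(np.asarray(true), np.asarray(pred), n)
    out = counts.copy()
    tp, tn = counts["TP"].astype(float), counts["TN"].astype(float)
    fp, fn = counts["FP"].astype(float), counts["FN"].astype(float)
    out["SE"] = [
        _safe_div(t, t + f) for t, f in zip(tp, fn)
    ]
    out["SP"] = [_safe_div(t, t + f) for t, f in zip(tn, fp)]
    out["ACC"] = (tp + tn) / (tp + tn + fp + fn)
    mcc = []
    for a, b, c, d in zip(tp, tn, fp, fn):
        denom = math.sqrt((a + c) * (a + d) * (b + c) * (b + d))
        mcc.append(_safe_div(a * b - c * d, denom))
    out["MCC"] = mcc
    out["success_rate"] = out["SE"]  # per-class success rate T(i)/N(i)
    total = len(true)
    overall = float(counts["TP"].sum()) / total if total else 0.0
    return MetricsReport(
        per_class=out,
        overall_success_rate=overall,
        config=dict(config or {}),
    )


def stratified_kfold(
    y: Sequence[int], K: int, repeats: int = 1, seed: int = 0
) -> list[list[np.ndarray]]:
    """Stratified K-fold test-index sets for each of ``repeats`` partitions.

    Within every class the members are shuffled and dealt cyclically, so
    per-class counts across folds differ by at most one; folds are disjoint
    and cover the dataset.  Classes smaller than K trigger a warning and a
    best-effort assignment (some folds simply lack that class).
    """
    y = np.asarray(y)
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if K > y.size:
        raise ValueError(f"K={K} exceeds dataset size {y.size}")
    classes, class_counts = np.unique(y, return_counts=True)
    small = classes[class_counts < K]
    if small.size:
        warnings.warn(
            f"classes {small.tolist()} have fewer than K={K} members; "
            "stratification is best-effort",
            stacklevel=2,
        )
    partitions: list[list[np.ndarray]] = []
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        folds: list[list[int]] = [[] for _ in range(K)]
        fill = np.zeros(K, dtype=int)
        for c in classes:
            members = np.flatnonzero(y == c)
            rng.shuffle(members)
            # deal to the currently least-filled folds for near-equal sizes
            order = np.lexsort((rng.permutation(K), fill))
            for j, m in enumerate(members):
                folds[order[j % K]].append(int(m))
            fill = np.array([len(f) for f in folds])
        partitions.append([np.array(sorted(f), dtype=int) for f in folds])
    return partitions


def _run_partition(
    estimator, X: np.ndarray, y: np.ndarray, folds: list[np.ndarray], k_grid
) -> dict[int, np.ndarray]:
    """Pooled predictions over one partition, for every k in k_grid."""
    N = y.size
    preds = {k: np.empty(N, dtype=int) for k in k_grid}
    for test_idx in folds:
        train_mask = np.ones(N, dtype=bool)
        train_mask[test_idx] = False
        model = clone(estimator)
        model.fit(X[train_mask], y[train_mask])
        for k in k_grid:
            model.k = k
            preds[k][test_idx] = model.predict(X[test_idx])
    return preds


def cross_validate(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    K: int = 10,
    repeats: int = 5,
    k_grid: Iterable[int] | None = None,
    seed: int = 0,
) -> MetricsReport:
    """Repeated stratified K-fold CV with neighbourhood-size selection.

    For every repeat and fold, all trainable stages of ``estimator`` (an
    unfitted classifier exposing a ``k`` parameter, e.g. CosineKNN or
    BalancedFusionKNN) are fitted on the training folds only and the
    held-out fold is predicted; predictions are pooled per repeat, metrics
    averaged over repeats.  The k in ``k_grid`` with the highest mean
    overall success rate is reported, along with its full averaged report.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = int(y.max())
    k_grid = sorted(k_grid) if k_grid is not None else [getattr(estimator, "k", 1)]
    partitions = stratified_kfold(y, K, repeats=repeats, seed=seed)
    max_train = y.size - max(len(f) for f in partitions[0])
    k_grid = [k for k in k_grid if k <= max_train]
    if not k_grid:
        raise ValueError("every k in k_grid exceeds the training-fold size")
    # per k: list over repeats of (overall, per_class frame)
    overall_by_k: dict[int, list[float]] = {k: [] for k in k_grid}
    frames_by_k: dict[int, list[pd.DataFrame]] = {k: [] for k in k_grid}
    for folds in partitions:
        preds = _run_partition(estimator, X, y, folds, k_grid)
        for k in k_grid:
            rep = compute_metrics(y, preds[k], n)
            overall_by_k[k].append(rep.overall_success_rate)
            frames_by_k[k].append(rep.per_class)
    mean_overall = {k: float(np.mean(v)) for k, v in overall_by_k.items()}
    best_k = max(k_grid, key=lambda k: (mean_overall[k], -k))
    mean_frame = (
        pd.concat(frames_by_k[best_k]).groupby(level=0).mean()
    )
    return MetricsReport(
        per_class=mean_frame,
        overall_success_rate=mean_overall[best_k],
        config={"K": K, "repeats": repeats, "k": best_k, "seed": seed},
        per_repeat_overall=overall_by_k[best_k],
        per_k_overall=mean_overall,
        per_k_repeat_overall=overall_by_k,
    )


def jackknife(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    k_grid: Iterable[int] | None = None,
) -> MetricsReport:
    """Leave-one-out evaluation; deterministic for a given dataset."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    N = y.size
    if N < 3:
        raise ValueError(f"jackknife needs N >= 3, got {N}")
    n = int(y.max())
    k_grid = sorted(k_grid) if k_grid is not None else [getattr(estimator, "k", 1)]
    k_grid = [k for k in k_grid if k <= N - 1]
    folds = [np.array([i]) for i in range(N)]
    preds = _run_partition(estimator, X, y, folds, k_grid)
    overall = {k: float(np.mean(preds[k] == y)) for k in k_grid}
    best_k = max(k_grid, key=lambda k: (overall[k], -k))
    rep = compute_metrics(y, preds[best_k], n, config={"protocol": "jackknife", "k": best_k})
    rep.per_k_overall = overall
    return rep
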