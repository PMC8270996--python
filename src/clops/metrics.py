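"""Evaluation bookkeeping: the R matrix and backward-transfer metrics.

R_j^i is the AUC on task j's test split measured right after training on the
i-th task finishes (defined for i ≥ j).  From it:

    average AUC = (1/N) Σ_j R_j^N
    BWT         = (1/(N−1)) Σ_{j<N} (R_j^N − R_j^j)
    BWT_t       = (1/(N−t)) Σ_{j≤N−t} (R_j^{j+t} − R_j^j)
    BWT_λ       = (1/(N−1)) Σ_{j<N} mean_t (R_j^{j+t} − R_j^j)

Positive backward transfer means training later tasks *helped* earlier ones
(constructive interference); negative means catastrophic forgetting.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["RMatrix", "average_auc", "bwt", "bwt_t", "bwt_lambda", "task_auc"]


class RMatrix:
    """Lower-triangular grid of scores; entry (j, i) = R_j^i, 0-based, i ≥ j."""

    def __init__(self, n_tasks: int):
        if n_tasks < 1:
            raise ValueError("need at least one task")
        self.n_tasks = n_tasks
        self.R = np.full((n_tasks, n_tasks), np.nan)

    def set(self, task_j: int, after_i: int, value: float) -> None:
        if after_i < task_j:
            raise ValueError("R_j^i is defined for i >= j only")
        if not 0.0 <= value <= 1.0:
            raise ValueError("AUC entries must lie in [0, 1]")
        self.R[task_j, after_i] = value

    def get(self, task_j: int, after_i: int) -> float:
        return float(self.R[task_j, after_i])

    def final_column(self) -> np.ndarray:
        return self.R[:, -1]

    def as_array(self) -> np.ndarray:
        return self.R.copy()


def _as_matrix(R) -> np.ndarray:
    return R.as_array() if isinstance(R, RMatrix) else np.asarray(R, dtype=np.float64)


def average_auc(R) -> float:
    """Mean final-column score: performance on every task at the end of the stream."""
    M = _as_matrix(R)
    final = M[:, -1]
    if np.any(np.isnan(final)):
        raise ValueError("final column incomplete")
    return float(final.mean())


def bwt(R) -> float:
    """Standard backward transfer: final minus just-after-training, averaged."""
    M = _as_matrix(R)
    N = M.shape[0]
    if N < 2:
        raise ValueError("BWT needs at least two tasks")
    deltas = M[: N - 1, -1] - np.diag(M)[: N - 1]
    return float(deltas.mean())


def bwt_t(R, t: int) -> float:
    """Backward transfer measured exactly t tasks after each task's training."""
    M = _as_matrix(R)
    N = M.shape[0]
    if not 1 <= t <= N - 1:
        raise ValueError("t must be in [1, N-1]")
    j = np.arange(N - t)
    deltas = M[j, j + t] - M[j, j]
    return float(deltas.mean())


def bwt_lambda(R) -> float:
    """Backward transfer over all horizons: per-task mean delta, then task mean."""
    M = _as_matrix(R)
    N = M.shape[0]
    if N < 2:
        raise ValueError("BWT_lambda needs at least two tasks")
    per_task = []
    for j in range(N - 1):
        t = np.arange(1, N - j)
        per_task.append(float((M[j, j + t] - M[j, j]).mean()))
    return float(np.mean(per_task))


def task_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC of class-probability scores on one task's test split.

    Binary tasks use the standard ROC AUC of the positive-class probability;
    multi-class tasks use macro one-vs-rest AUC over the classes present.
    ``scores`` is (n, C) with columns ordered by sorted class label;
    ``labels`` holds local class indices into those columns.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("task AUC needs at least two classes in the test split")
    if scores.shape[1] == 2:
        return float(roc_auc_score(labels, scores[:, 1]))
    if len(present) < scores.shape[1]:
        # restrict to observed classes and renormalise
        sub = scores[:, present]
        sub = sub / sub.sum(axis=1, keepdims=True)
        remap = {c: i for i, c in enumerate(present)}
        labels = np.array([remap[c] for c in labels])
        scores = sub
    if scores.shape[1] == 2:
        return float(roc_auc_score(labels, scores[:, 1]))
    return float(roc_auc_score(labels, scores, multi_class="ovr", average="macro"))
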