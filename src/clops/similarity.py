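"""Task difficulty, pairwise similarity, and task-ordering curricula.

Each task's storage scores s_ik are summarised by a Gaussian fit
N(μ_k, σ_k²); task difficulty is d_k = 1/μ_k (low mean area = hard task).
Similarity between two tasks comes from the Hellinger distance between
their Gaussians, via the closed-form Bhattacharyya coefficient:

    BC(j, k) = sqrt(2 σ_j σ_k / (σ_j² + σ_k²)) · exp(−¼ (μ_j − μ_k)² / (σ_j² + σ_k²))
    S(j, k)  = 1 − sqrt(1 − BC)           (= 1 − Hellinger distance)

so S ∈ [0, 1], S = 1 for identical Gaussians, symmetric.  A curriculum is a
greedy chain: start at the easiest task (anti-curriculum: hardest), then
repeatedly append the not-yet-visited task most similar to the one just
added; ties break on the smaller task id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TaskGaussian",
    "fit_task_gaussian",
    "similarity",
    "similarity_matrix",
    "build_curriculum",
]


@dataclass(frozen=True)
class TaskGaussian:
    task_id: int
    mu: float
    sigma: float

    @property
    def difficulty(self) -> float:
        return 1.0 / self.mu


def fit_task_gaussian(task_id: int, s_values: np.ndarray) -> TaskGaussian:
    """Sample mean / sd (ddof=1) of a task's storage scores; degenerate fits rejected."""
    s = np.asarray(s_values, dtype=np.float64)
    if s.size < 2:
        raise ValueError("need at least two storage scores")
    mu = float(s.mean())
    sigma = float(s.std(ddof=1))
    if sigma == 0.0:
        raise ValueError("degenerate storage-score distribution (zero variance)")
    if mu == 0.0 or not np.isfinite(mu):
        raise ValueError("degenerate storage-score distribution (zero mean)")
    return TaskGaussian(task_id, mu, sigma)


def similarity(gj: TaskGaussian, gk: TaskGaussian) -> float:
    """Hellinger-based similarity between two task Gaussians, in [0, 1]."""
    if gj.sigma <= 0 or gk.sigma <= 0:
        raise ValueError("standard deviations must be positive")
    var_sum = gj.sigma**2 + gk.sigma**2
    bc = np.sqrt(2.0 * gj.sigma * gk.sigma / var_sum) * np.exp(
        -0.25 * (gj.mu - gk.mu) ** 2 / var_sum
    )
    bc = min(bc, 1.0)  # guard rounding at identical parameters
    return float(1.0 - np.sqrt(1.0 - bc))


def similarity_matrix(gaussians: list[TaskGaussian]) -> np.ndarray:
    """Symmetric N×N similarity matrix with unit diagonal."""
    n = len(gaussians)
    S = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            S[a, b] = S[b, a] = similarity(gaussians[a], gaussians[b])
    return S


def build_curriculum(
    S: np.ndarray,
    difficulties: np.ndarray,
    mode: str,
    task_ids: list[int] | None = None,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Order tasks by greedy similarity chaining.

    mode 'curriculum' starts from the easiest task (smallest d), mode
    'anti_curriculum' from the hardest; mode 'random' is a seeded shuffle.
    Returns a permutation of the task ids.
    """
    S = np.asarray(S, dtype=np.float64)
    d = np.asarray(difficulties, dtype=np.float64)
    n = len(d)
    if S.shape != (n, n):
        raise ValueError("similarity matrix and difficulty vector sizes differ")
    ids = list(task_ids) if task_ids is not None else list(range(n))
    if len(ids) != n:
        raise ValueError("task_ids length mismatch")
    if mode == "random":
        if rng is None:
            raise ValueError("random mode needs a generator")
        return [ids[i] for i in rng.permutation(n)]
    if mode == "curriculum":
        cur = int(np.lexsort((ids, d))[0])  # argmin d, ties by task id
    elif mode == "anti_curriculum":
        cur = int(np.lexsort((ids, -d))[0])
    else:
        raise ValueError(f"unknown curriculum mode {mode!r}")
    order = [cur]
    remaining = set(range(n)) - {cur}
    while remaining:
        # most similar to the most recently added task; ties by task id
        best = min(remaining, key=lambda m: (-S[order[-1], m], ids[m]))
        order.append(best)
        remaining.remove(best)
    return [ids[i] for i in order]
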