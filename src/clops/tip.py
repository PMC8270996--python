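"""Task-instance parameters: learnable per-instance loss coefficients.

Every training instance i of the current task k carries a coefficient
β_ik, initialised to 1 so the objective starts as a standard mean loss:

    L_current = (1/B_k) Σ_i [ β_ik · L_ik + λ (β_ik − 1)² ]

Replayed instances from earlier tasks enter unweighted:

    L_replay = (1/(B − B_k)) Σ_j Σ_i L_ij ,     L_total = L_current + L_replay.

β is learned by gradient descent on the same objective; since
∂L_current/∂β_ik = (1/B_k)(L_ik + 2λ(β_ik − 1)), hard instances (large
persistent loss) push β down while the quadratic regulariser (λ, default 10)
anchors it near 1.  The β value at each epoch boundary is recorded, and the
area under the trajectory (trapezoidal rule, Δt = one epoch) becomes the
storage score s_ik used to rank instances for the replay buffer: high s =
consistently easy, low s = consistently hard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BetaTable",
    "current_task_loss",
    "replay_loss",
    "update_betas",
    "storage_score",
    "loss_area_score",
]


def current_task_loss(
    per_instance_losses: np.ndarray, betas: np.ndarray, lam: float
) -> float:
    """Weighted, regularised mean loss over the current-task portion of a batch."""
    L = np.asarray(per_instance_losses, dtype=np.float64)
    b = np.asarray(betas, dtype=np.float64)
    if L.shape != b.shape or L.ndim != 1 or L.size == 0:
        raise ValueError("losses and betas must be equal-length 1-D arrays")
    if np.any(L < 0):
        raise ValueError("per-instance losses must be non-negative")
    return float(np.mean(b * L + lam * (b - 1.0) ** 2))


def replay_loss(per_instance_losses: np.ndarray) -> float:
    """Unweighted mean loss over replayed instances; 0 for an empty replay set."""
    L = np.asarray(per_instance_losses, dtype=np.float64)
    if L.size == 0:
        return 0.0
    if np.any(L < 0):
        raise ValueError("per-instance losses must be non-negative")
    return float(np.mean(L))


def update_betas(
    betas: np.ndarray, per_instance_losses: np.ndarray, lam: float, eta: float
) -> np.ndarray:
    """One gradient-descent step on β for a batch of B_k current-task instances.

    Gradient of the implemented objective:  (1/B_k)(L_i + 2λ(β_i − 1)).
    With λ = 0 and L_i > 0 every β_i strictly decreases.
    """
    b = np.asarray(betas, dtype=np.float64)
    L = np.asarray(per_instance_losses, dtype=np.float64)
    if b.shape != L.shape:
        raise ValueError("betas and losses must have the same shape")
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(L))):
        raise ValueError("betas and losses must be finite")
    grad = (L + 2.0 * lam * (b - 1.0)) / b.size
    return b - eta * grad


def storage_score(trajectory: np.ndarray, dt: float = 1.0) -> float:
    """Area under a β trajectory via the trapezoidal rule.

    ``trajectory`` holds β(0)..β(τ) at epoch boundaries; a constant-1
    trajectory of length τ+1 scores exactly τ.
    """
    traj = np.asarray(trajectory, dtype=np.float64)
    if traj.ndim != 1 or traj.size < 2:
        raise ValueError("trajectory needs at least two points")
    return float(np.trapezoid(traj, dx=dt))


def loss_area_score(loss_trajectory: np.ndarray, dt: float = 1.0) -> float:
    """Area under a per-instance loss trajectory (same trapezoid).

    Used by the alternative storage strategy, which keeps the instances with
    the *smallest* area (consistently easy ones).
    """
    return storage_score(loss_trajectory, dt)


@dataclass
class BetaTable:
    """β values and per-epoch trajectories for the current task's instances."""

    eta: float
    lam: float
    beta: dict[str, float] = field(default_factory=dict)
    trajectory: dict[str, list[float]] = field(default_factory=dict)

    def register(self, instance_ids: list[str]) -> None:
        for iid in instance_ids:
            self.beta[iid] = 1.0
            self.trajectory[iid] = [1.0]  # β(0) = 1

    def get(self, instance_ids: list[str]) -> np.ndarray:
        return np.array([self.beta[i] for i in instance_ids])

    def apply_update(self, instance_ids: list[str], losses: np.ndarray) -> None:
        new = update_betas(self.get(instance_ids), losses, self.lam, self.eta)
        for iid, val in zip(instance_ids, new):
            self.beta[iid] = float(val)

    def snapshot_epoch(self) -> None:
        """Record every instance's β at an epoch boundary."""
        for iid, val in self.beta.items():
            self.trajectory[iid].append(val)

    def storage_scores(self) -> dict[str, float]:
        return {iid: storage_score(np.asarray(tr)) for iid, tr in self.trajectory.items()}
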