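"""Replay buffer: importance-guided storage, uncertainty-guided acquisition.

When training on a task finishes, the ⌈b·N_k⌉ training instances with the
largest storage scores s_ik (easiest by the β-trajectory criterion) enter
that task's buffer slot; slots are per task and never evict one another, so
total capacity is Σ_k ⌈b·N_k⌉.  During later tasks, every buffered instance
is scored with BALD over T Monte-Carlo dropout passes,

    BALD = H(p̄) − (1/T) Σ_t H(p_t) ,   p̄ = mean posterior over the T passes,

(natural-log entropies; non-negative by Jensen's inequality, zero iff all
passes agree) and the ⌈a·slot⌉ highest-BALD instances of each task form the
acquisition pool actually replayed.  Random variants of both mechanisms,
with identical cardinalities, serve as ablation strategies.

All ties break lexicographically on instance id, so selections are
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import check_posterior_tensor
from .signal_data import LabeledSegment, TaskDataset

__all__ = [
    "BufferEntry",
    "ReplayBuffer",
    "bald_mcd",
    "acquire",
    "random_acquire",
]


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def bald_mcd(G: np.ndarray) -> np.ndarray:
    """BALD score per instance from an M×T×C posterior tensor.

    Entropy of the MC-mean posterior minus the mean per-pass entropy —
    the mutual information between prediction and the dropout mask.
    """
    G = check_posterior_tensor(G)
    p_bar = G.mean(axis=1)  # (M, C)
    h_mean = -_xlogx(p_bar).sum(axis=-1)
    h_each = -_xlogx(G).sum(axis=-1).mean(axis=1)
    return h_mean - h_each


def _top_fraction(ids: list[str], score: dict[str, float], frac: float) -> list[str]:
    """⌈frac·n⌉ ids with the largest scores; ties by lexicographic id."""
    n_keep = min(math.ceil(frac * len(ids)), len(ids))
    ranked = sorted(ids, key=lambda i: (-score[i], i))
    return ranked[:n_keep]


@dataclass
class BufferEntry:
    segment: LabeledSegment
    s: float
    stored_epoch: int = -1
    bald: float = float("nan")


@dataclass
class ReplayBuffer:
    """Per-task slots of stored segments with their s and BALD scores."""

    b: float
    slots: dict[int, dict[str, BufferEntry]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.b <= 1.0:
            raise ValueError("storage fraction b must be in (0, 1]")

    # -- storage -----------------------------------------------------------
    def store_task(
        self, task: TaskDataset, scores: dict[str, float], epoch: int = -1
    ) -> None:
        """Keep the top-s ⌈b·N_k⌉ training instances of a finished task."""
        train = task.split_segments("train")
        ids = [seg.instance_id for seg in train]
        missing = [i for i in ids if i not in scores]
        if missing:
            raise KeyError(f"missing storage score for {missing[0]!r}")
        keep = set(_top_fraction(ids, scores, self.b))
        self.slots[task.task_id] = {
            seg.instance_id: BufferEntry(seg, scores[seg.instance_id], epoch)
            for seg in train
            if seg.instance_id in keep
        }

    def store_task_random(
        self, task: TaskDataset, rng: np.random.Generator, epoch: int = -1
    ) -> None:
        """Ablation: store a uniform-random subset of identical size."""
        train = sorted(task.split_segments("train"), key=lambda s: s.instance_id)
        n_keep = min(math.ceil(self.b * len(train)), len(train))
        chosen = rng.choice(len(train), size=n_keep, replace=False)
        self.slots[task.task_id] = {
            train[i].instance_id: BufferEntry(train[i], float("nan"), epoch)
            for i in sorted(chosen)
        }

    def store_task_loss_area(
        self, task: TaskDataset, areas: dict[str, float], epoch: int = -1
    ) -> None:
        """Alternative storage: keep the ⌈b·N_k⌉ *smallest* loss-area instances."""
        neg = {i: -a for i, a in areas.items()}
        self.store_task(task, neg, epoch)

    # -- views -------------------------------------------------------------
    def task_ids(self) -> list[int]:
        return sorted(self.slots)

    def slot_ids(self, task_id: int) -> list[str]:
        return sorted(self.slots[task_id])

    def all_segments(self) -> list[LabeledSegment]:
        return [
            e.segment
            for k in self.task_ids()
            for e in (self.slots[k][i] for i in self.slot_ids(k))
        ]

    def total_size(self) -> int:
        return sum(len(s) for s in self.slots.values())

    def set_bald(self, scores: dict[str, float]) -> None:
        for slot in self.slots.values():
            for iid, entry in slot.items():
                if iid in scores:
                    entry.bald = scores[iid]

    def manifest_rows(self) -> list[dict]:
        return [
            {
                "task_id": k,
                "instance_id": iid,
                "s": self.slots[k][iid].s,
                "bald": self.slots[k][iid].bald,
                "stored_epoch": self.slots[k][iid].stored_epoch,
            }
            for k in self.task_ids()
            for iid in self.slot_ids(k)
        ]


def acquire(
    buffer: ReplayBuffer, bald_scores: dict[str, float], a: float
) -> dict[int, list[str]]:
    """Per task, the ⌈a·slot⌉ highest-BALD instance ids (the acquisition pool)."""
    if not 0.0 < a <= 1.0:
        raise ValueError("acquisition fraction a must be in (0, 1]")
    pool: dict[int, list[str]] = {}
    for k in buffer.task_ids():
        ids = buffer.slot_ids(k)
        missing = [i for i in ids if i not in bald_scores]
        if missing:
            raise KeyError(f"missing BALD score for {missing[0]!r}")
        pool[k] = _top_fraction(ids, bald_scores, a)
    return pool


def random_acquire(
    buffer: ReplayBuffer, a: float, rng: np.random.Generator
) -> dict[int, list[str]]:
    """Ablation: uniform-random pool of identical per-task cardinality."""
    if not 0.0 < a <= 1.0:
        raise ValueError("acquisition fraction a must be in (0, 1]")
    pool: dict[int, list[str]] = {}
    for k in buffer.task_ids():
        ids = buffer.slot_ids(k)
        n_keep = min(math.ceil(a * len(ids)), len(ids))
        chosen = rng.choice(len(ids), size=n_keep, replace=False)
        pool[k] = [ids[i] for i in sorted(chosen)]
    return pool
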