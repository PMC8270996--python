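"""Desk-scale study definitions shared by the test suite and result scripts.

These functions pin down one set of scaled-down study conditions — a 4-task
class-incremental stream of 4-second segments at 100 Hz, a two-block
convolutional trunk, 20 epochs per task — and run the three experiments the
package is built around:

- :func:`forgetting_study`      fine-tuning vs the replay strategy vs the
                                fully random ablation, multi-seed;
- :func:`curriculum_study`      curriculum-ordered vs random-ordered training;
- :func:`difficulty_recovery`   label-flip parameter recovery: do corrupted
                                instances receive lower storage scores?

Everything is deterministic given the seed arguments.
"""

from __future__ import annotations

import numpy as np

from .network import ClassifierSpec
from .signal_data import SyntheticConfig, make_stream
from .trainer import TrainConfig, run_stream

__all__ = [
    "desk_stream",
    "desk_spec",
    "desk_config",
    "forgetting_study",
    "curriculum_study",
    "difficulty_recovery",
]

# 4-second single-lead segments at 100 Hz: long enough to hold several beats
# of every class in the palette, small enough that a full continual run takes
# seconds on one CPU core.
DESK_L = 400
DESK_FS = 100.0


def desk_stream(seed: int = 0, n_classes: int = 8) -> object:
    """The scaled-down class-incremental stream (n_classes/2 binary tasks)."""
    cfg = SyntheticConfig(
        n_classes=n_classes, L=DESK_L, fs=DESK_FS, seed=seed
    )
    return make_stream("class_il", cfg)


def desk_spec() -> ClassifierSpec:
    """Two conv blocks (8 and 16 channels, kernel 7, pool 4), dropout 0.3."""
    return ClassifierSpec(channels=(8, 16), kernels=(7, 7), pool=4, dropout=0.3)


def desk_config(strategy: str, seed: int, **overrides) -> TrainConfig:
    """Training configuration of the scaled-down studies.

    τ = 20 epochs per task, batch size 8, learning rate 1e-2 (the small
    trunk takes few optimizer steps per task, so it trains an order of
    magnitude hotter than a full-scale model would), λ = 10, b = 0.25,
    a = 0.5, T = 20 MC passes.
    """
    kw = dict(
        strategy=strategy,
        tau=20,
        batch_size=8,
        lr=1e-2,
        model_spec=desk_spec(),
        seed=seed,
        record_val_auc=False,
    )
    kw.update(overrides)
    return TrainConfig(**kw)


def forgetting_study(seeds, stream=None) -> dict:
    """Fine-tuning vs replay vs random-both on the class-incremental stream.

    Returns per-strategy lists of average AUC and BWT across seeds.
    """
    stream = stream if stream is not None else desk_stream()
    out: dict = {}
    for strategy in ("fine_tuning", "clops", "random_both"):
        aucs, bwts = [], []
        for seed in seeds:
            log = run_stream(stream, desk_config(strategy, seed))
            aucs.append(log.metrics["average_auc"])
            bwts.append(log.metrics["bwt"])
        out[strategy] = {"average_auc": aucs, "bwt": bwts}
    return out


def curriculum_study(seeds, stream=None) -> dict:
    """Curriculum-ordered vs random-ordered replay training, per seed."""
    stream = stream if stream is not None else desk_stream()
    out = {"curriculum": {"bwt": [], "average_auc": [], "orders": []},
           "random": {"bwt": [], "average_auc": [], "orders": []}}
    for seed in seeds:
        for mode in ("curriculum", "random"):
            log = run_stream(
                stream, desk_config("clops", seed, task_order=mode)
            )
            out[mode]["bwt"].append(log.metrics["bwt"])
            out[mode]["average_auc"].append(log.metrics["average_auc"])
            out[mode]["orders"].append(log.task_order)
    return out


def difficulty_recovery(seeds, flip_fraction: float = 0.2) -> dict:
    """Label-flip recovery on one easily learnable binary task.

    The task pairs a normal-rate rhythm with a tachycardia, so clean
    instances are classified quickly; a ``flip_fraction`` of training labels
    is swapped, making those instances persistently hard.  Per seed, the
    mean storage score of flipped vs clean instances is compared; the
    difficulty interpretation of the task-instance parameters predicts the
    flipped mean is lower.
    """
    from .signal_data import DEFAULT_CLASS_PALETTE

    easy_pair = (DEFAULT_CLASS_PALETTE[0], DEFAULT_CLASS_PALETTE[4])
    results = {"s_flipped": [], "s_clean": [], "wins": 0}
    for seed in seeds:
        cfg = SyntheticConfig(
            n_classes=2, L=DESK_L, fs=DESK_FS, seed=seed, palette=easy_pair
        )
        stream = make_stream("class_il", cfg)
        train = sorted(
            stream.tasks[0].split_segments("train"), key=lambda s: s.instance_id
        )
        rng = np.random.default_rng(1_000 + seed)
        flip = rng.choice(
            len(train), size=int(round(flip_fraction * len(train))), replace=False
        )
        flipped = set()
        for i in flip:
            train[i].label = 1 - train[i].label
            flipped.add(train[i].instance_id)
        log = run_stream(stream, desk_config("clops", seed))
        s_f = float(np.mean(
            [r["s"] for r in log.s_rows if r["instance_id"] in flipped]
        ))
        s_c = float(np.mean(
            [r["s"] for r in log.s_rows if r["instance_id"] not in flipped]
        ))
        results["s_flipped"].append(s_f)
        results["s_clean"].append(s_c)
        results["wins"] += int(s_f < s_c)
    return results
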