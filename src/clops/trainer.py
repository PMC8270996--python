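"""Sequential training over a task stream under a continual-learning strategy.

Strategies
----------
``clops``               β-weighted loss, top-s storage, BALD acquisition
``fine_tuning``         plain mean loss, no buffer (the naive baseline)
``mtl``                 all tasks pooled and trained at once (upper baseline)
``random_storage``      random storage, BALD acquisition (ablation)
``random_acquisition``  top-s storage, random acquisition (ablation)
``random_both``         both mechanisms random (ablation)
``loss_area_storage``   stores smallest area-under-loss instances instead of top-s

Schedule: each task trains for τ epochs.  On global epochs ≥ τ_MC the whole
buffer is rescored with BALD over T Monte-Carlo dropout passes; on global
epochs ≥ τ_S the acquisition pool is refreshed from those scores.  The
defaults τ_MC = τ+1 and τ_S = τ+2 satisfy the required ordering
τ_S ≥ τ_MC > τ and make replay active from (almost) the first epoch after
the first task.  Each mini-batch then mixes B current-task instances with
B_r instances drawn uniformly from the pool; the replayed instances enter
the loss unweighted with coefficient 1/B_r.

Evaluation: after each task, the test split of every task trained so far is
scored (AUC), filling one column of the R matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import metrics as M
from .buffer import ReplayBuffer, acquire, bald_mcd, random_acquire
from .network import ClassifierSpec, ECGConvNet
from .signal_data import TaskDataset, TaskStream
from .similarity import build_curriculum, fit_task_gaussian, similarity_matrix
from .tip import BetaTable, loss_area_score

__all__ = ["TrainConfig", "RunLog", "run_stream", "curriculum_order"]

STRATEGIES = (
    "clops",
    "fine_tuning",
    "mtl",
    "random_storage",
    "random_acquisition",
    "random_both",
    "loss_area_storage",
)
_BETA_STRATEGIES = set(STRATEGIES) - {"fine_tuning", "mtl"}
_STORAGE_MODE = {
    "clops": "s",
    "random_acquisition": "s",
    "random_storage": "random",
    "random_both": "random",
    "loss_area_storage": "loss_area",
}
_ACQ_MODE = {
    "clops": "bald",
    "random_storage": "bald",
    "loss_area_storage": "bald",
    "random_acquisition": "random",
    "random_both": "random",
}


@dataclass
class TrainConfig:
    strategy: str = "clops"
    tau: int = 20
    tau_mc: int | None = None       # default tau + 1
    tau_s: int | None = None        # default tau + 2
    batch_size: int = 16
    replay_batch_size: int | None = None  # default batch_size
    lr: float = 1e-3
    beta_lr: float | None = None    # default lr
    lam: float = 10.0
    b: float = 0.25
    a: float = 0.5
    T: int = 20
    seed: int = 0
    task_order: object = None       # None | list[int] | 'curriculum' | 'anti_curriculum' | 'random'
    model_spec: ClassifierSpec | None = None
    record_val_auc: bool = True

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.tau_mc is None:
            self.tau_mc = self.tau + 1
        if self.tau_s is None:
            self.tau_s = self.tau + 2
        if not self.tau_s >= self.tau_mc > self.tau:
            raise ValueError(
                f"schedule must satisfy tau_s >= tau_mc > tau, got "
                f"tau_s={self.tau_s}, tau_mc={self.tau_mc}, tau={self.tau}"
            )
        if self.replay_batch_size is None:
            self.replay_batch_size = self.batch_size
        if self.beta_lr is None:
            self.beta_lr = self.lr
        if not 0 < self.b <= 1 or not 0 < self.a <= 1:
            raise ValueError("fractions b and a must be in (0, 1]")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class RunLog:
    scenario: str
    strategy: str
    task_order: list[int]
    rmatrix: M.RMatrix
    epochs: list[dict] = field(default_factory=list)
    s_rows: list[dict] = field(default_factory=list)
    buffer_rows: list[dict] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    def finalize(self) -> None:
        self.metrics["average_auc"] = M.average_auc(self.rmatrix)
        N = self.rmatrix.n_tasks
        if N >= 2 and self.strategy != "mtl":
            self.metrics["bwt"] = M.bwt(self.rmatrix)
            self.metrics["bwt_t"] = {t: M.bwt_t(self.rmatrix, t) for t in range(1, N)}
            self.metrics["bwt_lambda"] = M.bwt_lambda(self.rmatrix)


class _HeadManager:
    """Maps stream tasks to model heads and global labels to head-local indices."""

    def __init__(self, model: ECGConvNet, stream: TaskStream):
        self.model = model
        self.per_task = stream.head_policy == "per_task"
        self.shared_classes = stream.all_classes()
        self.task_classes = {
            t.task_id: sorted(t.class_set) for t in stream.tasks
        }
        if not self.per_task:
            model.add_head("shared", len(self.shared_classes))

    def head_of(self, task_id: int):
        if self.per_task:
            self.model.add_head(task_id, len(self.task_classes[task_id]))
            return task_id
        return "shared"

    def localize(self, task_id: int, labels: np.ndarray) -> np.ndarray:
        classes = (
            self.task_classes[task_id] if self.per_task else self.shared_classes
        )
        lut = {c: i for i, c in enumerate(classes)}
        return np.array([lut[int(y)] for y in labels])


def _segments_xy(segments) -> tuple[np.ndarray, np.ndarray, list[str]]:
    X = np.stack([s.signal for s in segments])
    y = np.array([s.label for s in segments])
    return X, y, [s.instance_id for s in segments]


def _evaluate_task(model, heads: _HeadManager, task: TaskDataset) -> float:
    test = task.split_segments("test")
    X, y, _ = _segments_xy(test)
    head = heads.head_of(task.task_id)
    probs = model.predict_proba(X, head)
    return M.task_auc(probs, heads.localize(task.task_id, y))


def _rescore_buffer(model, heads: _HeadManager, buf: ReplayBuffer,
                    T: int, seed: int) -> dict[str, float]:
    scores: dict[str, float] = {}
    for k in buf.task_ids():
        ids = buf.slot_ids(k)
        segs = [buf.slots[k][i].segment for i in ids]
        X = np.stack([s.signal for s in segs])
        G = model.mc_sample(X, T, heads.head_of(k), seed=seed + k)
        for iid, val in zip(ids, bald_mcd(G)):
            scores[iid] = float(val)
    buf.set_bald(scores)
    return scores


def _draw_replay(pool: dict[int, list[str]], buf: ReplayBuffer, n: int,
                 rng: np.random.Generator):
    """Uniform draw of up to n instances from the flattened pool, grouped by task."""
    flat = [(k, iid) for k in sorted(pool) for iid in pool[k]]
    if not flat:
        return []
    take = min(n, len(flat))
    idx = rng.choice(len(flat), size=take, replace=False)
    chosen: dict[int, list[str]] = {}
    for i in sorted(idx):
        k, iid = flat[i]
        chosen.setdefault(k, []).append(iid)
    groups = []
    for k, iids in chosen.items():
        segs = [buf.slots[k][i].segment for i in iids]
        groups.append((k, segs, take))
    return groups


def run_stream(stream: TaskStream, config: TrainConfig) -> RunLog:
    """Train over the stream under ``config.strategy`` and log everything."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.model_spec or ClassifierSpec(head_policy=stream.head_policy)
    if spec.head_policy != stream.head_policy:
        spec = replace(spec, head_policy=stream.head_policy)
    model = ECGConvNet(spec, lr=cfg.lr, seed=int(rng.integers(2**31)))
    heads = _HeadManager(model, stream)

    if cfg.strategy == "mtl":
        return _run_mtl(stream, cfg, model, heads, rng)

    order = _resolve_order(stream, cfg, rng)
    n_tasks = len(order)
    log = RunLog(stream.scenario, cfg.strategy, order, M.RMatrix(n_tasks))
    use_buffer = cfg.strategy in _STORAGE_MODE
    buf = ReplayBuffer(cfg.b) if use_buffer else None
    pool: dict[int, list[str]] | None = None
    bald_scores: dict[str, float] = {}
    global_epoch = 0

    for pos, tid in enumerate(order):
        task = stream.tasks[tid]
        train = sorted(task.split_segments("train"), key=lambda s: s.instance_id)
        X, y_raw, ids = _segments_xy(train)
        head = heads.head_of(tid)
        y = heads.localize(tid, y_raw)
        n = len(train)

        use_beta = cfg.strategy in _BETA_STRATEGIES
        betas = BetaTable(eta=cfg.beta_lr, lam=cfg.lam)
        if use_beta:
            betas.register(ids)
        loss_traj: dict[str, list[float]] | None = None
        if cfg.strategy == "loss_area_storage":
            init = model.per_instance_losses(X, y, head)
            loss_traj = {iid: [float(v)] for iid, v in zip(ids, init)}

        for _ in range(cfg.tau):
            global_epoch += 1
            if buf is not None and buf.total_size():
                if global_epoch >= cfg.tau_mc and _ACQ_MODE[cfg.strategy] == "bald":
                    bald_scores = _rescore_buffer(
                        model, heads, buf, cfg.T, seed=int(rng.integers(2**31))
                    )
                if global_epoch >= cfg.tau_s:
                    if _ACQ_MODE[cfg.strategy] == "bald":
                        pool = acquire(buf, bald_scores, cfg.a)
                    else:
                        pool = random_acquire(buf, cfg.a, rng)

            perm = rng.permutation(n)
            ep_loss, ep_replay, n_batches = 0.0, 0.0, 0
            for start in range(0, n, cfg.batch_size):
                sel = perm[start : start + cfg.batch_size]
                ids_b = [ids[i] for i in sel]
                beta_b = betas.get(ids_b) if use_beta else np.ones(len(sel))
                groups = [(X[sel], y[sel], head, beta_b / len(sel))]
                replay_groups = (
                    _draw_replay(pool, buf, cfg.replay_batch_size, rng)
                    if pool else []
                )
                for k, segs, take in replay_groups:
                    Xr = np.stack([s.signal for s in segs])
                    yr = heads.localize(k, np.array([s.label for s in segs]))
                    groups.append(
                        (Xr, yr, heads.head_of(k), np.full(len(segs), 1.0 / take))
                    )
                losses = model.train_step(groups, rng)
                if use_beta:
                    betas.apply_update(ids_b, losses[0])
                if loss_traj is not None:
                    for iid, v in zip(ids_b, losses[0]):
                        loss_traj[iid].append(float(v))
                ep_loss += float(np.mean(losses[0]))
                if len(losses) > 1:
                    ep_replay += float(np.mean(np.concatenate(losses[1:])))
                n_batches += 1
            if use_beta:
                betas.snapshot_epoch()

            rec = {
                "global_epoch": global_epoch,
                "task": tid,
                "train_loss": ep_loss / n_batches,
                "replay_loss": ep_replay / n_batches,
            }
            if cfg.record_val_auc:
                rec["val_auc"] = {
                    order[q]: _val_auc(model, heads, stream.tasks[order[q]])
                    for q in range(pos + 1)
                }
            log.epochs.append(rec)

        # task finished: score, store, evaluate
        if use_beta:
            s_scores = betas.storage_scores()
            for seg in train:
                log.s_rows.append(
                    {
                        "instance_id": seg.instance_id,
                        "task_id": tid,
                        "label": seg.label,
                        "s": s_scores[seg.instance_id],
                    }
                )
        if buf is not None:
            mode = _STORAGE_MODE[cfg.strategy]
            if mode == "s":
                buf.store_task(task, s_scores, epoch=global_epoch)
            elif mode == "random":
                buf.store_task_random(task, rng, epoch=global_epoch)
            else:  # loss_area: keep smallest-area instances
                areas = {
                    iid: loss_area_score(np.asarray(tr))
                    for iid, tr in loss_traj.items()
                }
                buf.store_task_loss_area(task, areas, epoch=global_epoch)
        for q in range(pos + 1):
            log.rmatrix.set(q, pos, _evaluate_task(model, heads, stream.tasks[order[q]]))

    if buf is not None:
        log.buffer_rows = buf.manifest_rows()
    log.finalize()
    return log


def _val_auc(model, heads, task) -> float:
    val = task.split_segments("val")
    X, y, _ = _segments_xy(val)
    probs = model.predict_proba(X, heads.head_of(task.task_id))
    try:
        return M.task_auc(probs, heads.localize(task.task_id, y))
    except ValueError:
        return float("nan")


def _run_mtl(stream, cfg, model, heads, rng) -> RunLog:
    """Pool every task's training data and train once with a shared head."""
    classes = stream.all_classes()
    model.add_head("mtl", len(classes))
    lut = {c: i for i, c in enumerate(classes)}
    segs = [
        s
        for t in stream.tasks
        for s in sorted(t.split_segments("train"), key=lambda s: s.instance_id)
    ]
    X, y_raw, _ = _segments_xy(segs)
    y = np.array([lut[int(v)] for v in y_raw])
    n = len(segs)
    order = list(range(stream.n_tasks))
    log = RunLog(stream.scenario, "mtl", order, M.RMatrix(stream.n_tasks))
    for epoch in range(1, cfg.tau + 1):
        perm = rng.permutation(n)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            sel = perm[start : start + cfg.batch_size]
            w = np.full(len(sel), 1.0 / len(sel))
            losses = model.train_step([(X[sel], y[sel], "mtl", w)], rng)
            ep_loss += float(np.mean(losses[0]))
            n_batches += 1
        log.epochs.append(
            {"global_epoch": epoch, "task": -1, "train_loss": ep_loss / n_batches,
             "replay_loss": 0.0}
        )
    for j, task in enumerate(stream.tasks):
        test = task.split_segments("test")
        Xt, yt, _ = _segments_xy(test)
        probs = model.predict_proba(Xt, "mtl")
        y_local = np.array([lut[int(v)] for v in yt])
        log.rmatrix.set(j, stream.n_tasks - 1, M.task_auc(probs, y_local))
    log.metrics["average_auc"] = M.average_auc(log.rmatrix)
    return log


def _resolve_order(stream: TaskStream, cfg: TrainConfig,
                   rng: np.random.Generator) -> list[int]:
    if cfg.task_order is None:
        return [t.task_id for t in stream.tasks]
    if isinstance(cfg.task_order, (list, tuple)):
        order = list(cfg.task_order)
        if sorted(order) != sorted(t.task_id for t in stream.tasks):
            raise ValueError("task_order must be a permutation of the stream's tasks")
        return order
    if cfg.task_order == "random":
        ids = [t.task_id for t in stream.tasks]
        return [ids[i] for i in rng.permutation(len(ids))]
    if cfg.task_order in {"curriculum", "anti_curriculum"}:
        return curriculum_order(stream, cfg, cfg.task_order)
    raise ValueError(f"unknown task_order {cfg.task_order!r}")


def curriculum_order(stream: TaskStream, config: TrainConfig, mode: str) -> list[int]:
    """Derive a task order from a pilot run's storage-score distributions.

    Runs the stream once in its native order to collect s values, fits one
    Gaussian per task, and chains tasks greedily by Hellinger similarity
    starting from the easiest (curriculum) or hardest (anti-curriculum) task.
    """
    pilot_cfg = replace(config, task_order=None, record_val_auc=False)
    if pilot_cfg.strategy not in _BETA_STRATEGIES:
        pilot_cfg = replace(pilot_cfg, strategy="clops")
    pilot = run_stream(stream, pilot_cfg)
    ids = sorted({row["task_id"] for row in pilot.s_rows})
    gaussians = [
        fit_task_gaussian(
            k, np.array([r["s"] for r in pilot.s_rows if r["task_id"] == k])
        )
        for k in ids
    ]
    S = similarity_matrix(gaussians)
    d = np.array([g.difficulty for g in gaussians])
    return build_curriculum(S, d, mode, task_ids=ids)
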