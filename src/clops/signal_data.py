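"""Synthetic single-lead ECG segments and continual-learning task streams.

The generator builds quasi-periodic traces as sums of Gaussian wavelets
(P, Q, R, S, T per beat) on a flat baseline, with beat onsets drawn from a
configured heart rate and RR jitter, an optional ST-segment offset between
the S and T wavelets, and additive white noise.  Classes differ in rate, RR
irregularity, QRS width, ST offset and P/T-wave amplitude, which is enough
morphological structure for a small convolutional classifier to separate
them while leaving hard instances near class boundaries.

Streams come in four flavours mirroring common continual-learning settings
for clinical time series:

- ``class_il``      consecutive disjoint class pairs, one binary task each,
                    with a classification head per task;
- ``time_il``       three "terms" whose class prevalences and noise level
                    drift (seasonal shift), shared head;
- ``domain_il``     twelve lead-like scalar projections of one latent trace
                    (different sensors viewing the same electrical source),
                    shared head;
- ``institute_il``  tasks with disjoint label vocabularies, different
                    sampling rates and noise (different hospitals), signals
                    resampled to a common length, shared head.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabeledSegment",
    "TaskDataset",
    "TaskStream",
    "SyntheticConfig",
    "DEFAULT_CLASS_PALETTE",
    "ClassMorphology",
    "synthesize_segment",
    "make_stream",
    "write_stream",
    "read_stream",
    "read_wfdb_record",
    "CorruptStreamError",
]

SCENARIOS = ("class_il", "time_il", "domain_il", "institute_il")
SPLITS = ("train", "val", "test")


class CorruptStreamError(RuntimeError):
    """Raised when a stored stream's manifest and signal container disagree."""


@dataclass(frozen=True)
class ClassMorphology:
    """Per-class beat morphology parameters.

    rate_bpm        mean heart rate (beats per minute)
    rr_cv           coefficient of variation of the RR interval (0 = metronomic)
    qrs_width_s     width (seconds) scale of the QRS complex wavelets
    st_offset       additive level of the ST segment (mV-like units)
    p_amp, t_amp    amplitudes of the P and T wavelets (0 = absent wave)
    """

    rate_bpm: float
    rr_cv: float
    qrs_width_s: float
    st_offset: float
    p_amp: float
    t_amp: float
    r_amp: float = 1.0
    q_amp: float = -0.12
    s_amp: float = -0.22

    def validate(self) -> None:
        if self.rate_bpm <= 0:
            raise ValueError(f"heart rate must be positive, got {self.rate_bpm}")
        if not 0.0 <= self.rr_cv < 1.0:
            raise ValueError(f"RR coefficient of variation must be in [0, 1), got {self.rr_cv}")
        if self.qrs_width_s <= 0:
            raise ValueError("QRS width must be positive")


# A 12-class palette organised as six clinically confusable pairs: within a
# pair the rhythms share heart rate and differ in exactly one morphological
# feature (ST level, P-wave presence, QRS width, RR regularity, T amplitude).
# Real arrhythmia label sets are confusable in exactly this way, which is what
# makes sequential binary tasks compete for the same learned features.
DEFAULT_CLASS_PALETTE: tuple[ClassMorphology, ...] = (
    ClassMorphology(70, 0.05, 0.08, 0.00, 0.15, 0.30),   # normal sinus rhythm
    ClassMorphology(70, 0.05, 0.08, 0.12, 0.15, 0.30),   # ... with ST elevation
    ClassMorphology(48, 0.06, 0.08, 0.00, 0.15, 0.30),   # sinus bradycardia
    ClassMorphology(48, 0.06, 0.08, 0.00, 0.00, 0.30),   # junctional (no P wave)
    ClassMorphology(160, 0.04, 0.08, 0.00, 0.00, 0.25),  # narrow-QRS tachycardia
    ClassMorphology(160, 0.04, 0.14, 0.00, 0.00, 0.25),  # wide-QRS tachycardia
    ClassMorphology(95, 0.30, 0.08, 0.00, 0.00, 0.30),   # irregular (AF-like)
    ClassMorphology(95, 0.05, 0.08, 0.00, 0.00, 0.30),   # regular, same rate
    ClassMorphology(70, 0.05, 0.08, -0.12, 0.15, 0.30),  # ST depression
    ClassMorphology(70, 0.05, 0.08, 0.00, 0.15, 0.08),   # flattened T wave
    ClassMorphology(130, 0.20, 0.13, 0.00, 0.00, 0.25),  # fast wide irregular
    ClassMorphology(130, 0.04, 0.13, 0.00, 0.00, 0.25),  # fast wide regular
)


@dataclass
class LabeledSegment:
    """One fixed-length single-lead signal with its label and bookkeeping ids."""

    signal: np.ndarray
    label: int
    task_id: int
    instance_id: str
    split: str
    patient_id: str | None = None
    source_id: str | None = None
    fs: float = 250.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 1:
            raise ValueError("segment signal must be one-dimensional")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("segment signal contains non-finite values")
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")


@dataclass
class TaskDataset:
    """All segments of one task, with the set of class labels it exposes."""

    task_id: int
    segments: list[LabeledSegment]
    class_set: frozenset[int] = field(default=frozenset())

    def __post_init__(self) -> None:
        observed = frozenset(s.label for s in self.segments)
        if not self.class_set:
            self.class_set = observed
        elif self.class_set != observed:
            raise ValueError("class_set does not match observed labels")
        for s in self.segments:
            if s.task_id != self.task_id:
                raise ValueError("segment task_id mismatch")

    def split_segments(self, split: str) -> list[LabeledSegment]:
        return [s for s in self.segments if s.split == split]

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class TaskStream:
    """Ordered sequence of tasks plus the head policy the scenario implies."""

    scenario: str
    tasks: list[TaskDataset]
    head_policy: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "class_il":
            if self.head_policy != "per_task":
                raise ValueError("class_il requires per-task heads")
            seen: set[int] = set()
            for t in self.tasks:
                if seen & t.class_set:
                    raise ValueError("class_il tasks must have disjoint class sets")
                seen |= t.class_set
        elif self.head_policy != "shared":
            raise ValueError(f"{self.scenario} requires a shared head")
        ids = [s.instance_id for t in self.tasks for s in t.segments]
        if len(ids) != len(set(ids)):
            raise ValueError("instance ids must be unique across the stream")

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    def all_classes(self) -> list[int]:
        return sorted(set().union(*(t.class_set for t in self.tasks)))


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic stream generator.

    ``n_train``/``n_val``/``n_test`` count segments per class per task.
    Each synthetic patient contributes ``segments_per_patient`` segments and
    belongs to exactly one split, so splits are patient-disjoint.
    """

    n_classes: int = 12
    L: int = 2500
    fs: float = 250.0
    noise_sd: float = 0.25
    n_train: int = 24
    n_val: int = 8
    n_test: int = 32
    seed: int = 0
    segments_per_patient: int = 2
    palette: tuple[ClassMorphology, ...] = DEFAULT_CLASS_PALETTE

    def __post_init__(self) -> None:
        if self.n_classes < 2 or self.n_classes > len(self.palette):
            raise ValueError(
                f"n_classes must be in [2, {len(self.palette)}], got {self.n_classes}"
            )
        if self.L <= 0 or self.fs <= 0:
            raise ValueError("L and fs must be positive")
        if min(self.n_train, self.n_val, self.n_test) <= 0:
            raise ValueError("per-split counts must be positive")
        for m in self.palette:
            m.validate()


# Wavelet timing relative to the R peak (seconds).  P/T widths and offsets
# are fixed; QRS widths scale with the class parameter.
_P_OFFSET, _P_WIDTH = -0.20, 0.025
_Q_OFFSET = -0.040
_S_OFFSET = 0.040
_T_OFFSET, _T_WIDTH = 0.30, 0.07
_ST_START, _ST_END = 0.06, 0.24  # ST segment window after the R peak


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def synthesize_segment(
    class_params: ClassMorphology,
    noise_sd: float,
    L: int,
    fs: float,
    seed: int,
    return_onsets: bool = False,
):
    """Generate one synthetic single-lead trace.

    Returns the length-``L`` signal; with ``return_onsets=True`` also returns
    the R-peak sample positions actually placed (the beat-onset log).
    Deterministic given ``seed``.
    """
    if L <= 0 or fs <= 0:
        raise ValueError("L and fs must be positive")
    class_params.validate()
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    rr_mean = 60.0 / class_params.rate_bpm  # seconds per beat
    duration = L / fs
    t = np.arange(L) / fs

    # Place R peaks: first at half an RR interval, then successive RR draws.
    onsets: list[float] = []
    pos = 0.5 * rr_mean
    while pos < duration + rr_mean:
        onsets.append(pos)
        rr = rr_mean * (1.0 + class_params.rr_cv * rng.standard_normal())
        pos += max(rr, 0.2 * rr_mean)  # refractory floor keeps beats ordered
    onset_arr = np.asarray(onsets)

    qrs_w = class_params.qrs_width_s
    sig = np.zeros(L)
    for r in onset_arr:
        sig += class_params.p_amp * _gauss(t, r + _P_OFFSET, _P_WIDTH)
        sig += class_params.q_amp * _gauss(t, r + _Q_OFFSET * (qrs_w / 0.08), qrs_w / 6.0)
        sig += class_params.r_amp * _gauss(t, r, qrs_w / 5.0)
        sig += class_params.s_amp * _gauss(t, r + _S_OFFSET * (qrs_w / 0.08), qrs_w / 6.0)
        sig += class_params.t_amp * _gauss(t, r + _T_OFFSET, _T_WIDTH)
        if class_params.st_offset != 0.0:
            # Smooth plateau between the S and T wavelets.
            rise = 1.0 / (1.0 + np.exp(-(t - (r + _ST_START)) / 0.01))
            fall = 1.0 / (1.0 + np.exp(-((r + _ST_END) - t) / 0.01))
            sig += class_params.st_offset * rise * fall
    if noise_sd > 0:
        sig += noise_sd * rng.standard_normal(L)

    r_samples = np.round(onset_arr[onset_arr < duration] * fs).astype(int)
    r_samples = r_samples[r_samples < L]
    if return_onsets:
        return sig, r_samples
    return sig


# ---------------------------------------------------------------------------
# Stream assembly
# ---------------------------------------------------------------------------

def _split_plan(cfg: SyntheticConfig) -> list[tuple[str, int]]:
    """Per class: (split, index-within-split) for every segment, patient-blocked."""
    plan = []
    for split, n in (("train", cfg.n_train), ("val", cfg.n_val), ("test", cfg.n_test)):
        plan.extend((split, i) for i in range(n))
    return plan


def _patient_of(cfg: SyntheticConfig, split: str, cls: int, idx: int) -> str:
    # Patients never straddle splits: the patient index is local to the split.
    return f"{split}-c{cls}-p{idx // cfg.segments_per_patient}"


def _gen_class_segments(
    cfg: SyntheticConfig,
    cls: int,
    task_id: int,
    seed_base: int,
    noise_sd: float | None = None,
    L: int | None = None,
    fs: float | None = None,
    label: int | None = None,
    prefix: str = "",
) -> list[LabeledSegment]:
    """All segments of one class for one task."""
    L = cfg.L if L is None else L
    fs = cfg.fs if fs is None else fs
    noise_sd = cfg.noise_sd if noise_sd is None else noise_sd
    label = cls if label is None else label
    out = []
    for j, (split, idx) in enumerate(_split_plan(cfg)):
        seed = (seed_base * 1_000_003 + cls * 7919 + j) % (2**31)
        sig = synthesize_segment(cfg.palette[cls], noise_sd, L, fs, seed)
        iid = f"{prefix}t{task_id}-c{cls}-{split}{idx:03d}"
        out.append(
            LabeledSegment(
                signal=sig,
                label=label,
                task_id=task_id,
                instance_id=iid,
                split=split,
                patient_id=_patient_of(cfg, split, cls, idx),
                source_id=f"c{cls}-{split}{idx:03d}",
                fs=fs,
            )
        )
    return out


def time_il_prevalences(n_classes: int) -> np.ndarray:
    """Class-prevalence vectors for the three drifting terms (rows sum to 1).

    Term 1 emphasises the low-index classes, term 3 the high-index ones;
    term 2 is flat — a simple seasonal drift of the label marginal.
    """
    idx = np.arange(n_classes, dtype=float)
    ramps = np.stack(
        [n_classes - idx, np.ones(n_classes) * (n_classes / 2.0), idx + 1.0]
    )
    return ramps / ramps.sum(axis=1, keepdims=True)


TIME_IL_NOISE = (0.06, 0.10, 0.14)  # per-term noise sd drift

# Lead-like scalar gains for the 12 projections (cosines of spread electrode
# angles; sign flips included so leads genuinely differ).
DOMAIN_LEAD_GAINS = tuple(np.round(np.cos(np.linspace(0, np.pi, 12) + 0.2), 4))
DOMAIN_LEAD_NOISE = 0.04


def make_stream(scenario: str, config: SyntheticConfig) -> TaskStream:
    """Assemble the task stream for one continual-learning scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    cfg = config
    if cfg.n_classes < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(cfg.seed)

    if scenario == "class_il":
        if cfg.n_classes % 2 != 0:
            raise ValueError("class_il requires an even number of classes")
        tasks = []
        for k in range(cfg.n_classes // 2):
            segs = []
            for cls in (2 * k, 2 * k + 1):
                segs.extend(_gen_class_segments(cfg, cls, k, seed_base=cfg.seed + k))
            tasks.append(TaskDataset(task_id=k, segments=segs))
        return TaskStream("class_il", tasks, "per_task")

    if scenario == "time_il":
        prev = time_il_prevalences(cfg.n_classes)
        total_per_split = {
            "train": cfg.n_train * cfg.n_classes,
            "val": cfg.n_val * cfg.n_classes,
            "test": cfg.n_test * cfg.n_classes,
        }
        tasks = []
        for term in range(3):
            segs = []
            for split, n_total in total_per_split.items():
                # Largest-remainder allocation of n_total segments to classes.
                raw = prev[term] * n_total
                counts = np.floor(raw).astype(int)
                rem = n_total - counts.sum()
                order = np.argsort(-(raw - counts))
                counts[order[:rem]] += 1
                for cls, n_cls in enumerate(counts):
                    for idx in range(n_cls):
                        seed = int(rng.integers(2**31))
                        sig = synthesize_segment(
                            cfg.palette[cls], TIME_IL_NOISE[term], cfg.L, cfg.fs, seed
                        )
                        iid = f"t{term}-c{cls}-{split}{idx:03d}"
                        segs.append(
                            LabeledSegment(
                                sig, cls, term, iid, split,
                                patient_id=_patient_of(cfg, split, cls, idx),
                                source_id=iid, fs=cfg.fs,
                            )
                        )
            tasks.append(TaskDataset(task_id=term, segments=segs))
        return TaskStream(
            "time_il", tasks, "shared",
            meta={"prevalences": prev, "noise_sd": TIME_IL_NOISE},
        )

    if scenario == "domain_il":
        # One latent trace per (class, split, index); 12 gain projections of it.
        latents: list[tuple[str, int, str, np.ndarray, str]] = []
        for cls in range(cfg.n_classes):
            for j, (split, idx) in enumerate(_split_plan(cfg)):
                seed = (cfg.seed * 1_000_003 + cls * 7919 + j) % (2**31)
                sig = synthesize_segment(cfg.palette[cls], 0.0, cfg.L, cfg.fs, seed)
                latents.append(
                    (f"c{cls}-{split}{idx:03d}", cls, split, sig,
                     _patient_of(cfg, split, cls, idx))
                )
        tasks = []
        for lead, gain in enumerate(DOMAIN_LEAD_GAINS):
            segs = []
            for src, cls, split, latent, pid in latents:
                noise = DOMAIN_LEAD_NOISE * rng.standard_normal(cfg.L)
                segs.append(
                    LabeledSegment(
                        gain * latent + noise, cls, lead, f"lead{lead:02d}-{src}",
                        split, patient_id=pid, source_id=src, fs=cfg.fs,
                    )
                )
            tasks.append(TaskDataset(task_id=lead, segments=segs))
        return TaskStream(
            "domain_il", tasks, "shared", meta={"lead_gains": DOMAIN_LEAD_GAINS}
        )

    # institute_il: ≥3 sites with disjoint label vocabularies, different fs and
    # noise; everything resampled onto the common grid of length L.
    n_sites = 3
    if cfg.n_classes < n_sites:
        raise ValueError("institute_il needs at least one class per site")
    site_fs = (cfg.fs, cfg.fs * 1.4, cfg.fs * 0.8)
    site_noise = (cfg.noise_sd, cfg.noise_sd * 1.5, cfg.noise_sd * 0.75)
    class_chunks = np.array_split(np.arange(cfg.n_classes), n_sites)
    tasks = []
    for site in range(n_sites):
        fs_s, noise_s = site_fs[site], site_noise[site]
        L_native = int(round(cfg.L * fs_s / cfg.fs))
        segs = []
        for cls in class_chunks[site]:
            for seg in _gen_class_segments(
                cfg, int(cls), site, seed_base=cfg.seed + 101 * site,
                noise_sd=noise_s, L=L_native, fs=fs_s, prefix=f"site{site}-",
            ):
                grid_native = np.arange(L_native) / fs_s
                grid_common = np.arange(cfg.L) / cfg.fs
                seg.signal = np.interp(grid_common, grid_native, seg.signal)
                seg.fs = cfg.fs
                segs.append(seg)
        tasks.append(TaskDataset(task_id=site, segments=segs))
    return TaskStream(
        "institute_il", tasks, "shared",
        meta={"site_fs": site_fs, "site_noise": site_noise},
    )


# ---------------------------------------------------------------------------
# Persistence: CSV manifest + NPZ signal container
# ---------------------------------------------------------------------------

_MANIFEST_COLS = (
    "instance_id", "task_id", "label", "split", "patient_id", "source_id",
    "fs", "row",
)


def write_stream(stream: TaskStream, path: str) -> None:
    """Write a stream as ``manifest.csv`` + ``signals.npz`` under ``path``."""
    os.makedirs(path, exist_ok=True)
    rows, signals = [], []
    for task in stream.tasks:
        for seg in task.segments:
            rows.append(
                [seg.instance_id, task.task_id, seg.label, seg.split,
                 seg.patient_id or "", seg.source_id or "", repr(seg.fs),
                 len(signals)]
            )
            signals.append(seg.signal)
    with open(os.path.join(path, "manifest.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["scenario", stream.scenario, "head_policy", stream.head_policy])
        w.writerow(_MANIFEST_COLS)
        w.writerows(rows)
    np.savez(os.path.join(path, "signals.npz"), signals=np.asarray(signals))


def read_stream(path: str) -> TaskStream:
    """Inverse of :func:`write_stream`; round-trips signals bitwise."""
    with open(os.path.join(path, "manifest.csv"), newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        scenario, head_policy = header[1], header[3]
        cols = next(r)
        if tuple(cols) != _MANIFEST_COLS:
            raise CorruptStreamError("unexpected manifest columns")
        rows = list(r)
    with np.load(os.path.join(path, "signals.npz")) as z:
        signals = z["signals"]
    if len(rows) != len(signals):
        raise CorruptStreamError(
            f"manifest has {len(rows)} rows but container holds {len(signals)} signals"
        )
    by_task: dict[int, list[LabeledSegment]] = {}
    for iid, task_id, label, split, pid, src, fs, row in rows:
        idx = int(row)
        if idx >= len(signals):
            raise CorruptStreamError(f"row index {idx} out of range")
        by_task.setdefault(int(task_id), []).append(
            LabeledSegment(
                signals[idx], int(label), int(task_id), iid, split,
                patient_id=pid or None, source_id=src or None, fs=float(fs),
            )
        )
    tasks = [TaskDataset(k, by_task[k]) for k in sorted(by_task)]
    return TaskStream(scenario, tasks, head_policy)


# ---------------------------------------------------------------------------
# Minimal WFDB adapter (text .hea header + format-16 .dat), for real records
# ---------------------------------------------------------------------------

def read_wfdb_record(prefix: str, label: int = 0, task_id: int = 0,
                     split: str = "train") -> list[LabeledSegment]:
    """Read a WFDB record (format 16 only) into one segment per channel.

    ``prefix`` is the record path without extension; expects ``prefix.hea``
    and a little-endian int16 ``.dat`` with channels interleaved sample-major.
    Digital values are converted to physical units via (adc - baseline)/gain.
    """
    with open(prefix + ".hea") as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    record_name, n_sig = rec_fields[0], int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    gains, baselines, dat_file = [], [], None
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        dat_file = parts[0]
        if parts[1] not in {"16", "16+0"}:
            raise ValueError(f"unsupported WFDB signal format {parts[1]!r}")
        gain_spec = parts[2] if len(parts) > 2 else "200"
        if "(" in gain_spec:
            gain_str, base_str = gain_spec.split("(")
            baseline = int(base_str.rstrip(")").split("/")[0])
        else:
            gain_str, baseline = gain_spec, 0
        gain = float(gain_str.split("/")[0]) or 200.0
        gains.append(gain)
        baselines.append(baseline)
    raw = np.fromfile(
        os.path.join(os.path.dirname(prefix), dat_file), dtype="<i2"
    )
    if n_samp:
        raw = raw[: n_samp * n_sig]
    digital = raw.reshape(-1, n_sig)
    segs = []
    for ch in range(n_sig):
        phys = (digital[:, ch].astype(np.float64) - baselines[ch]) / gains[ch]
        segs.append(
            LabeledSegment(
                phys, label, task_id, f"{record_name}-ch{ch}", split,
                patient_id=record_name, source_id=record_name, fs=fs,
            )
        )
    return segs
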