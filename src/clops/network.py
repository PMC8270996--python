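"""Lightweight 1-D convolutional classifier with Monte-Carlo dropout.

The model is a small stack of same-padded 1-D convolution blocks
(conv → ReLU → max-pool), global average pooling over time, a single
dropout site on the penultimate feature vector, and one linear
classification head per task (or a single shared head).  Forward and
backward passes are written directly in NumPy (float64) with an Adam
optimizer; at this scale a tensor framework buys nothing and the explicit
implementation keeps every stochastic element reproducible from a seed.

The dropout site doubles as the stochastic mask for Monte-Carlo posterior
sampling: :meth:`ECGConvNet.mc_sample` repeats the head pass ``T`` times
with independent masks, producing the ``M × T × C`` posterior tensor that
the uncertainty-based buffer acquisition consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClassifierSpec", "ECGConvNet", "check_posterior_tensor"]


@dataclass
class ClassifierSpec:
    """Architecture hyperparameters.

    channels/kernels give one conv block per entry; ``pool`` is the max-pool
    window applied after each block; ``dropout`` is the rate p of the single
    dropout site on the penultimate representation (required: MC sampling
    needs at least one stochastic site, so p must lie strictly in (0, 1)).
    """

    channels: tuple[int, ...] = (16, 32, 64)
    kernels: tuple[int, ...] = (7, 7, 7)
    pool: int = 2
    dropout: float = 0.3
    head_policy: str = "shared"

    def __post_init__(self) -> None:
        if not 0.0 < self.dropout < 1.0:
            raise ValueError("dropout rate must be in (0, 1)")
        if len(self.channels) != len(self.kernels) or not self.channels:
            raise ValueError("channels and kernels must be equal-length, non-empty")
        if self.head_policy not in {"shared", "per_task"}:
            raise ValueError("head_policy must be 'shared' or 'per_task'")


def check_posterior_tensor(G: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Validate an M×T×C posterior tensor (each length-C slice on the simplex)."""
    G = np.asarray(G, dtype=np.float64)
    if G.ndim != 3:
        raise ValueError("posterior tensor must be M×T×C")
    if np.any(G < -atol) or np.any(np.abs(G.sum(axis=-1) - 1.0) > atol):
        raise ValueError("posterior slices must be probability vectors")
    return G


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _Adam:
    def __init__(self, lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


class ECGConvNet:
    """Conv trunk + dropout + per-task or shared linear heads."""

    def __init__(self, spec: ClassifierSpec, lr: float = 1e-3, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for i, (c_out, k) in enumerate(zip(spec.channels, spec.kernels)):
            fan_in = c_in * k
            self.params[f"W{i}"] = rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
            self.params[f"b{i}"] = np.zeros(c_out)
            c_in = c_out
        self.n_features = c_in
        self.heads: dict[object, int] = {}  # head id -> n classes
        self.opt = _Adam(lr)

    # -- heads -------------------------------------------------------------
    def add_head(self, head, n_classes: int) -> None:
        """Register a linear head; zero-initialised so an untrained head is uniform."""
        if head in self.heads:
            if self.heads[head] != n_classes:
                raise ValueError(f"head {head!r} already exists with a different size")
            return
        self.heads[head] = n_classes
        self.params[f"head_{head}_W"] = np.zeros((n_classes, self.n_features))
        self.params[f"head_{head}_b"] = np.zeros(n_classes)

    def _require_head(self, head) -> int:
        if head not in self.heads:
            raise KeyError(f"unknown head {head!r}")
        return self.heads[head]

    # -- forward -----------------------------------------------------------
    def _conv_forward(self, x: np.ndarray, i: int, cache: list | None):
        # x: (B, C_in, L); same padding, stride 1
        W, b = self.params[f"W{i}"], self.params[f"b{i}"]
        k = self.spec.kernels[i]
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, k - 1 - pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B,C,L,k)
        cols = win.transpose(0, 2, 1, 3).reshape(x.shape[0], x.shape[2], -1)
        out = cols @ W.T + b  # (B, L, C_out)
        out = out.transpose(0, 2, 1)
        if cache is not None:
            cache.append(("conv", i, cols, x.shape))
        return out

    def _trunk_forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """x: (B, L) → penultimate features (B, F)."""
        h = np.asarray(x, dtype=np.float64)[:, None, :]  # (B, 1, L)
        p = self.spec.pool
        for i in range(len(self.spec.channels)):
            h = self._conv_forward(h, i, cache)
            mask = h > 0
            h = h * mask
            if cache is not None:
                cache.append(("relu", mask))
            if p > 1:
                B, C, L = h.shape
                Lp = (L // p) * p
                r = h[:, :, :Lp].reshape(B, C, Lp // p, p)
                idx = r.argmax(axis=3)
                h2 = np.take_along_axis(r, idx[..., None], axis=3)[..., 0]
                if cache is not None:
                    cache.append(("pool", idx, (B, C, L, Lp)))
                h = h2
        feats = h.mean(axis=2)  # global average pool over time
        if cache is not None:
            cache.append(("gap", h.shape))
        return feats

    def _trunk_backward(self, dfeats: np.ndarray, cache: list,
                        grads: dict[str, np.ndarray]) -> None:
        tag, shape = cache.pop()
        assert tag == "gap"
        d = np.repeat(dfeats[:, :, None] / shape[2], shape[2], axis=2)
        while cache:
            entry = cache.pop()
            if entry[0] == "pool":
                _, idx, (B, C, L, Lp) = entry
                dr = np.zeros((B, C, Lp // self.spec.pool, self.spec.pool))
                np.put_along_axis(dr, idx[..., None], d[..., None], axis=3)
                dfull = np.zeros((B, C, L))
                dfull[:, :, :Lp] = dr.reshape(B, C, Lp)
                d = dfull
            elif entry[0] == "relu":
                d = d * entry[1]
            elif entry[0] == "conv":
                _, i, cols, x_shape = entry
                W = self.params[f"W{i}"]
                k = self.spec.kernels[i]
                dout = d.transpose(0, 2, 1)  # (B, L, C_out)
                grads[f"W{i}"] = grads.get(f"W{i}", 0) + np.einsum(
                    "blc,blf->cf", dout, cols
                )
                grads[f"b{i}"] = grads.get(f"b{i}", 0) + dout.sum(axis=(0, 1))
                dcols = dout @ W  # (B, L, C_in*k)
                B, _, L = x_shape
                c_in = x_shape[1]
                dcols = dcols.reshape(B, L, c_in, k)
                pad = k // 2
                dxp = np.zeros((B, c_in, L + k - 1))
                for kk in range(k):
                    dxp[:, :, kk : kk + L] += dcols[:, :, :, kk].transpose(0, 2, 1)
                d = dxp[:, :, pad : pad + L]

    def _head_logits(self, feats: np.ndarray, head) -> np.ndarray:
        self._require_head(head)
        return feats @ self.params[f"head_{head}_W"].T + self.params[f"head_{head}_b"]

    # -- public inference --------------------------------------------------
    def predict_proba(self, X: np.ndarray, head) -> np.ndarray:
        """Deterministic class probabilities (dropout inactive); rows on the simplex."""
        feats = self._trunk_forward(np.atleast_2d(X))
        return _softmax(self._head_logits(feats, head))

    def mc_sample(self, X: np.ndarray, T: int, head, seed: int) -> np.ndarray:
        """T stochastic dropout passes → posterior tensor of shape (M, T, C).

        The dropout site sits on the penultimate features, so the trunk is
        evaluated once and T independent inverted-dropout masks are applied
        before the head — identical in distribution to T full passes.
        """
        if T < 1:
            raise ValueError("T must be >= 1")
        C = self._require_head(head)
        rng = np.random.default_rng(seed)
        feats = self._trunk_forward(np.atleast_2d(X))
        p = self.spec.dropout
        G = np.empty((feats.shape[0], T, C))
        for t in range(T):
            mask = (rng.random(feats.shape) >= p) / (1.0 - p)
            G[:, t, :] = _softmax(self._head_logits(feats * mask, head))
        return G

    # -- training ----------------------------------------------------------
    def train_step(
        self,
        groups: list[tuple[np.ndarray, np.ndarray, object, np.ndarray]],
        rng: np.random.Generator,
    ) -> list[np.ndarray]:
        """One optimizer step on a mixed batch.

        Each group is (X, y_local, head, weight) where ``weight[i]`` is the
        coefficient of instance i's cross-entropy in the total objective
        (β_i/B_k for current-task instances, 1/B_r for replayed ones).
        Returns the per-instance *unweighted* cross-entropy losses per group,
        which drive the task-instance parameter updates and loss tracking.
        """
        X_all = np.concatenate([g[0] for g in groups], axis=0)
        cache: list = []
        feats = self._trunk_forward(X_all, cache)
        p = self.spec.dropout
        mask = (rng.random(feats.shape) >= p) / (1.0 - p)
        fdrop = feats * mask

        grads: dict[str, np.ndarray] = {}
        dfeats = np.zeros_like(feats)
        losses_out: list[np.ndarray] = []
        offset = 0
        for X, y, head, w in groups:
            n = len(y)
            f = fdrop[offset : offset + n]
            logits = self._head_logits(f, head)
            probs = _softmax(logits)
            ce = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None))
            losses_out.append(ce)
            dlogits = (probs - np.eye(probs.shape[1])[y]) * np.asarray(w)[:, None]
            key = f"head_{head}_"
            grads[key + "W"] = grads.get(key + "W", 0) + dlogits.T @ f
            grads[key + "b"] = grads.get(key + "b", 0) + dlogits.sum(axis=0)
            dfeats[offset : offset + n] = dlogits @ self.params[key + "W"]
            offset += n
        self._trunk_backward(dfeats * mask, cache, grads)
        self.opt.step(self.params, grads)
        return losses_out

    def per_instance_losses(self, X: np.ndarray, y: np.ndarray, head) -> np.ndarray:
        """Cross-entropy per instance with dropout inactive (no parameter update)."""
        probs = self.predict_proba(X, head)
        return -np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))
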