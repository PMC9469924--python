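"""Multitask text CNN (MtCNN) implemented directly on NumPy.

Architecture: a trainable word-embedding layer feeds three parallel 1-d
convolutions over time (filter widths of 3, 4 and 5 consecutive words in
the reference profile), each followed by ReLU; the per-filter activations
are global-max-pooled over time, concatenated, and sent through one dense
softmax head per classification task.  The multitask loss is the
unweighted sum over tasks of the mean categorical cross-entropy, which
accepts both hard (one-hot) and soft probability targets — the latter is
what ensemble distillation trains on.

Training uses minibatch Adam with early stopping on validation loss
(patience in epochs, best weights restored).  Gradients are exact: the
global max-pool routes the upstream gradient to the argmax time step of
each filter, so the backward pass touches only the winning windows.

The module exposes both a functional surface (``init_model`` /
``forward`` / ``train_model``) and a small model-object layer
(:class:`MultitaskTextCNN` whose ``fit`` returns :class:`MtCNNResults`).
"""

from __future__ import annotations

import io as _io
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import EncodedDocument, stack_encoded
from .types import TaskSchema

EPS = 1e-7  # probability clipping inside the cross-entropy


class ConfigurationError(ValueError):
    pass


class AlignmentError(ValueError):
    """Prediction/target containers disagree on document ids or order."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one MtCNN.

    The reference profile uses 300-dimensional embeddings and 300 filters
    for each of the widths (3, 4, 5); the desk profile shrinks these so a
    20-member ensemble trains in minutes on one CPU.
    """

    schema: TaskSchema
    vocab_size: int
    seq_len: int
    embedding_dim: int = 300
    filter_widths: tuple[int, ...] = (3, 4, 5)
    filters_per_width: int = 300
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if any(w > self.seq_len for w in self.filter_widths):
            raise ConfigurationError(
                f"filter widths {self.filter_widths} exceed sequence length {self.seq_len}"
            )
        if self.vocab_size < 2:
            raise ConfigurationError("vocab_size must include PAD and UNK")

    @property
    def pooled_dim(self) -> int:
        """Length of the concatenated max-pooled feature vector."""
        return len(self.filter_widths) * self.filters_per_width

    @classmethod
    def reference_profile(cls, vocab_size: int, seq_len: int, **kw) -> "ModelConfig":
        return cls(
            schema=TaskSchema.reference_profile(),
            vocab_size=vocab_size,
            seq_len=seq_len,
            embedding_dim=300,
            filter_widths=(3, 4, 5),
            filters_per_width=300,
            **kw,
        )


@dataclass
class ModelState:
    """All learnable weights plus training provenance."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    history: list[dict] = field(default_factory=list)
    seed: int = 0

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def checksum(self) -> int:
        h = 0
        for k in sorted(self.params):
            h = zlib.crc32(self.params[k].tobytes(), zlib.crc32(k.encode(), h))
        return h


@dataclass
class PredictionSet:
    """Per-document softmax probability vectors for every task."""

    ids: list[str]
    probs: dict[str, np.ndarray]  # task -> (N, K_t)

    def __post_init__(self) -> None:
        n = len(self.ids)
        for task, p in self.probs.items():
            if p.shape[0] != n:
                raise AlignmentError(f"task {task!r}: {p.shape[0]} rows for {n} ids")

    def argmax(self, task: str) -> np.ndarray:
        return self.probs[task].argmax(axis=1)

    def confidence(self, task: str) -> np.ndarray:
        """Maximum softmax entry per document (the abstention score)."""
        return self.probs[task].max(axis=1)

    def check_aligned(self, other: "PredictionSet") -> None:
        if self.ids != other.ids:
            raise AlignmentError("prediction sets are not aligned by document id")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def init_model(config: ModelConfig) -> ModelState:
    """Seed-deterministic Glorot-style initialization; the padding row of
    the embedding starts at zero."""
    rng = np.random.default_rng(config.seed)
    D, F, C = config.embedding_dim, config.filters_per_width, config.pooled_dim
    params: dict[str, np.ndarray] = {}
    emb = rng.uniform(-0.1, 0.1, size=(config.vocab_size, D)).astype(np.float32)
    emb[0] = 0.0
    params["embedding"] = emb
    for w in config.filter_widths:
        fan_in, fan_out = w * D, F
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        params[f"conv{w}_W"] = rng.uniform(-lim, lim, size=(fan_in, F)).astype(np.float32)
        params[f"conv{w}_b"] = np.zeros(F, dtype=np.float32)
    for name, K in config.schema:
        lim = np.sqrt(6.0 / (C + K))
        params[f"head_{name}_W"] = rng.uniform(-lim, lim, size=(C, K)).astype(np.float32)
        params[f"head_{name}_b"] = np.zeros(K, dtype=np.float32)
    return ModelState(config=config, params=params, seed=config.seed)


def _forward_batch(state: ModelState, X: np.ndarray, need_cache: bool = False):
    cfg = state.config
    p = state.params
    if X.shape[1] != cfg.seq_len:
        raise ValueError(f"expected sequence length {cfg.seq_len}, got {X.shape[1]}")
    E = p["embedding"][X]  # (B, L, D)
    pooled_parts, cache_parts = [], []
    for w in cfg.filter_widths:
        win = sliding_window_view(E, w, axis=1)  # (B, P, D, w)
        B, P = win.shape[0], win.shape[1]
        win = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, P, w * cfg.embedding_dim)
        act = np.maximum(win @ p[f"conv{w}_W"] + p[f"conv{w}_b"], 0.0)  # (B, P, F)
        amax = act.argmax(axis=1)  # (B, F)
        pooled = np.take_along_axis(act, amax[:, None, :], axis=1)[:, 0, :]
        pooled_parts.append(pooled)
        if need_cache:
            cache_parts.append((w, win, amax, pooled))
    H = np.concatenate(pooled_parts, axis=1)  # (B, C)
    logits = {name: H @ p[f"head_{name}_W"] + p[f"head_{name}_b"] for name, _ in cfg.schema}
    probs = {name: _softmax(z) for name, z in logits.items()}
    cache = {"X": X, "H": H, "parts": cache_parts} if need_cache else None
    return probs, cache


def forward(
    state: ModelState, docs: Sequence[EncodedDocument] | np.ndarray, batch_size: int = 256
) -> PredictionSet:
    """Softmax prediction vectors for every task on a document set."""
    if isinstance(docs, np.ndarray):
        ids = [str(i) for i in range(docs.shape[0])]
        X = docs
    else:
        ids, X, _ = stack_encoded(docs, state.config.schema)
    out = {name: [] for name, _ in state.config.schema}
    for i in range(0, X.shape[0], batch_size):
        probs, _ = _forward_batch(state, X[i : i + batch_size])
        for name in out:
            out[name].append(probs[name])
    probs = {
        name: (
            np.concatenate(chunks)
            if chunks
            else np.zeros((0, state.config.schema.n_classes_of(name)))
        )
        for name, chunks in out.items()
    }
    return PredictionSet(ids=ids, probs=probs)


def multitask_cross_entropy(
    targets: Mapping[str, np.ndarray], probs: Mapping[str, np.ndarray]
) -> float:
    """Sum over tasks of the mean per-document cross-entropy
    ``-sum_k y_k log yhat_k`` with probabilities clipped at ``EPS``.

    ``targets`` rows may be one-hot or soft; each must sum to 1.
    """
    total = 0.0
    for name, y in targets.items():
        yhat = np.clip(probs[name], EPS, 1.0)
        if y.shape != yhat.shape:
            raise AlignmentError(
                f"task {name!r}: targets {y.shape} vs predictions {yhat.shape}"
            )
        total += float(-(y * np.log(yhat)).sum(axis=1).mean())
    return total


def one_hot(labels: np.ndarray, K: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], K), dtype=np.float32)
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


class EarlyStopping:
    """Stop when the monitored loss has not improved its best value for
    ``patience`` consecutive epochs; remembers the best epoch."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ConfigurationError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch: int | None = None
        self.bad_epochs = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record an epoch's loss; return True if training should stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def _backward_batch(
    state: ModelState,
    probs: Mapping[str, np.ndarray],
    targets: Mapping[str, np.ndarray],
    cache: dict,
) -> dict[str, np.ndarray]:
    cfg = state.config
    p = state.params
    X, H = cache["X"], cache["H"]
    B = X.shape[0]
    grads: dict[str, np.ndarray] = {}
    dH = np.zeros_like(H)
    for name, _ in cfg.schema:
        dz = (probs[name] - targets[name]).astype(np.float32) / B  # mean-CE gradient
        grads[f"head_{name}_W"] = H.T @ dz
        grads[f"head_{name}_b"] = dz.sum(axis=0)
        dH += dz @ p[f"head_{name}_W"].T

    D = cfg.embedding_dim
    F = cfg.filters_per_width
    dE = np.zeros((B, cfg.seq_len, D), dtype=np.float32)
    offset = 0
    b_idx = np.arange(B)[:, None]
    for w, win, amax, pooled in cache["parts"]:
        g = dH[:, offset : offset + F].copy()
        g[pooled <= 0.0] = 0.0  # ReLU: no gradient when the max is clipped at 0
        offset += F
        # only the argmax window of each filter receives gradient
        sel = win[b_idx, amax]  # (B, F, w*D)
        grads[f"conv{w}_W"] = np.einsum("bfd,bf->df", sel, g).astype(np.float32)
        grads[f"conv{w}_b"] = g.sum(axis=0)
        contrib = g[:, :, None] * p[f"conv{w}_W"].T[None, :, :]  # (B, F, w*D)
        for o in range(w):
            np.add.at(dE, (b_idx, amax + o), contrib[:, :, o * D : (o + 1) * D])
    gE = np.zeros_like(p["embedding"])
    np.add.at(gE, X.reshape(-1), dE.reshape(-1, D))
    grads["embedding"] = gE
    return grads


def _as_targets(
    schema: TaskSchema,
    labels: Mapping[str, np.ndarray],
    soft: Mapping[str, np.ndarray] | None,
) -> dict[str, np.ndarray]:
    if soft is not None:
        return {name: np.asarray(soft[name], dtype=np.float32) for name, _ in schema}
    return {name: one_hot(labels[name], K) for name, K in schema}


def evaluate_loss(
    state: ModelState,
    X: np.ndarray,
    targets: Mapping[str, np.ndarray],
    batch_size: int = 256,
) -> float:
    """Mean multitask cross-entropy over a document set."""
    n = X.shape[0]
    total = 0.0
    for i in range(0, n, batch_size):
        probs, _ = _forward_batch(state, X[i : i + batch_size])
        sl = {k: v[i : i + batch_size] for k, v in targets.items()}
        total += multitask_cross_entropy(sl, probs) * min(batch_size, n - i)
    return total / n


def train_model(
    state: ModelState,
    train_docs: Sequence[EncodedDocument],
    val_docs: Sequence[EncodedDocument],
    soft_targets: Mapping[str, np.ndarray] | None = None,
    val_soft_targets: Mapping[str, np.ndarray] | None = None,
) -> ModelState:
    """Minibatch-Adam training with early stopping on validation loss.

    Training halts when the validation loss fails to improve its best
    value for ``patience`` consecutive epochs (or at ``max_epochs``); the
    weights of the best validation epoch are restored.  ``soft_targets``
    replaces the hard labels with per-task probability matrices aligned
    with ``train_docs`` — this is the distillation path, and one-hot soft
    targets reproduce hard-label training exactly.
    """
    if len(train_docs) == 0 or len(val_docs) == 0:
        raise ValueError("train and validation splits must be non-empty")
    cfg = state.config
    _, Xtr, ytr = stack_encoded(train_docs, cfg.schema)
    _, Xva, yva = stack_encoded(val_docs, cfg.schema)
    T_tr = _as_targets(cfg.schema, ytr, soft_targets)
    T_va = _as_targets(cfg.schema, yva, val_soft_targets)

    opt = _Adam(state.params, cfg.learning_rate)
    stopper = EarlyStopping(cfg.patience)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7261696E]))
    best_params = state.copy_params()
    n = Xtr.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            probs, cache = _forward_batch(state, Xtr[idx], need_cache=True)
            batch_t = {k: v[idx] for k, v in T_tr.items()}
            epoch_loss += multitask_cross_entropy(batch_t, probs) * len(idx)
            grads = _backward_batch(state, probs, batch_t, cache)
            opt.step(state.params, grads)
        val_loss = evaluate_loss(state, Xva, T_va)
        state.history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n, "val_loss": val_loss}
        )
        if val_loss < stopper.best:
            best_params = state.copy_params()
        if stopper.update(epoch, val_loss):
            break
    state.params = best_params
    return state


def save_checkpoint(state: ModelState, path: str | Path) -> None:
    """Single-file checkpoint: weights + config + seed + history."""
    cfg = state.config
    meta = {
        "schema": [[n, k] for n, k in cfg.schema],
        "vocab_size": cfg.vocab_size,
        "seq_len": cfg.seq_len,
        "embedding_dim": cfg.embedding_dim,
        "filter_widths": list(cfg.filter_widths),
        "filters_per_width": cfg.filters_per_width,
        "learning_rate": cfg.learning_rate,
        "batch_size": cfg.batch_size,
        "max_epochs": cfg.max_epochs,
        "patience": cfg.patience,
        "seed": cfg.seed,
        "history": state.history,
    }
    buf = _io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state.params)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> ModelState:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        params = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = ModelConfig(
        schema=TaskSchema([(n, k) for n, k in meta["schema"]]),
        vocab_size=meta["vocab_size"],
        seq_len=meta["seq_len"],
        embedding_dim=meta["embedding_dim"],
        filter_widths=tuple(meta["filter_widths"]),
        filters_per_width=meta["filters_per_width"],
        learning_rate=meta["learning_rate"],
        batch_size=meta["batch_size"],
        max_epochs=meta["max_epochs"],
        patience=meta["patience"],
        seed=meta["seed"],
    )
    return ModelState(config=cfg, params=params, history=meta["history"], seed=meta["seed"])


class MultitaskTextCNN:
    """Model-object layer over the functional MtCNN surface.

    Construct from a :class:`ModelConfig`, call :meth:`fit` with encoded
    train/validation documents (and optionally soft targets) and receive
    an :class:`MtCNNResults` carrying the trained state, the loss history
    and a ``summary()`` table.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.state = init_model(config)

    def fit(
        self,
        train_docs: Sequence[EncodedDocument],
        val_docs: Sequence[EncodedDocument],
        soft_targets: Mapping[str, np.ndarray] | None = None,
        val_soft_targets: Mapping[str, np.ndarray] | None = None,
    ) -> "MtCNNResults":
        state = train_model(self.state, train_docs, val_docs, soft_targets, val_soft_targets)
        return MtCNNResults(state, val_docs)


class MtCNNResults:
    """Fit results: trained weights, per-epoch loss history, diagnostics."""

    def __init__(self, state: ModelState, val_docs: Sequence[EncodedDocument]):
        self.state = state
        self._val_docs = list(val_docs)

    @property
    def history(self) -> list[dict]:
        return self.state.history

    @property
    def best_val_loss(self) -> float:
        return min(h["val_loss"] for h in self.history)

    def predict(self, docs: Sequence[EncodedDocument]) -> PredictionSet:
        return forward(self.state, docs)

    def val_accuracy(self) -> dict[str, float]:
        preds = self.predict(self._val_docs)
        _, _, y = stack_encoded(self._val_docs, self.state.config.schema)
        return {
            name: float((preds.argmax(name) == y[name]).mean())
            for name, _ in self.state.config.schema
        }

    def summary(self) -> str:
        cfg = self.state.config
        n_params = sum(v.size for v in self.state.params.values())
        lines = [
            "Multitask text CNN — fit summary",
            "=" * 40,
            f"tasks:            {', '.join(f'{n}({k})' for n, k in cfg.schema)}",
            f"embedding dim:    {cfg.embedding_dim}",
            f"filters:          {cfg.filters_per_width} x widths {cfg.filter_widths}",
            f"parameters:       {n_params}",
            f"epochs run:       {len(self.history)}",
            f"best val loss:    {self.best_val_loss:.4f}",
        ]
        for name, acc in self.val_accuracy().items():
            lines.append(f"val accuracy [{name}]: {acc:.4f}")
        return "\n".join(lines)
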