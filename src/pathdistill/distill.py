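"""Ensemble knowledge distillation via soft labels.

The teacher's averaged softmax vectors over the training documents become
probability targets ("soft labels") for a single student MtCNN with the
same architecture.  Soft labels carry the ensemble's uncertainty: a
document whose members split 50/50 between two classes yields a [0.5,
0.5, ...] target, which discourages the student from ever being fully
confident on it.  Label smoothing is provided as the uninformed baseline
soft-labeling scheme.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ensemble import EnsemblePool, aggregate
from .io import EncodedDocument
from .model import ModelConfig, ModelState, init_model, train_model


@dataclass
class SoftLabelSet:
    """Per-task probability targets for a document set, with provenance."""

    ids: list[str]
    targets: dict[str, np.ndarray]  # task -> (N, K_t)
    pool_hash: str = ""
    variant: str = "mean"

    def __post_init__(self) -> None:
        for task, y in self.targets.items():
            if y.shape[0] != len(self.ids):
                raise ValueError(f"task {task!r}: targets not aligned with ids")
            if not np.allclose(y.sum(axis=1), 1.0, atol=1e-5):
                raise ValueError(f"task {task!r}: soft-label rows must sum to 1")

    def save(self, prefix: str | Path) -> None:
        """Persist as a binary array container (.npz) plus a TSV id index;
        provenance (pool hash, aggregation variant) rides in the npz."""
        prefix = Path(prefix)
        meta = np.frombuffer(
            json.dumps({"pool_hash": self.pool_hash, "variant": self.variant}).encode(),
            dtype=np.uint8,
        )
        np.savez(prefix.with_suffix(".npz"), __meta__=meta, **self.targets)
        with prefix.with_suffix(".ids.tsv").open("w", encoding="utf-8") as fh:
            for i, doc_id in enumerate(self.ids):
                fh.write(f"{doc_id}\t{i}\n")

    @classmethod
    def load(cls, prefix: str | Path) -> "SoftLabelSet":
        prefix = Path(prefix)
        with np.load(prefix.with_suffix(".npz")) as z:
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            targets = {k: z[k] for k in z.files if k != "__meta__"}
        ids = [
            line.split("\t")[0]
            for line in prefix.with_suffix(".ids.tsv")
            .read_text(encoding="utf-8")
            .splitlines()
        ]
        return cls(ids=ids, targets=targets, **meta)

    def subset(self, ids: Sequence[str]) -> "SoftLabelSet":
        pos = {i: n for n, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"missing soft labels for ids {missing[:5]}")
        idx = np.array([pos[i] for i in ids])
        return SoftLabelSet(
            ids=list(ids),
            targets={t: y[idx] for t, y in self.targets.items()},
            pool_hash=self.pool_hash,
            variant=self.variant,
        )


def pool_fingerprint(pool: EnsemblePool) -> str:
    h = hashlib.sha256()
    for m in pool.members:
        h.update(str(m.checksum()).encode())
    return h.hexdigest()[:16]


def derive_soft_labels(
    pool: EnsemblePool,
    docs: Sequence[EncodedDocument],
    variant: str = "mean",
    batch_size: int = 256,
) -> SoftLabelSet:
    """Soft labels = the ensemble's aggregated prediction vector for each
    document; a deterministic function of the pool."""
    member_preds = pool.predict_members(docs, batch_size=batch_size)
    agg = aggregate(member_preds, variant=variant)
    return SoftLabelSet(
        ids=list(agg.ids),
        targets={t: p for t, p in agg.probs.items()},
        pool_hash=pool_fingerprint(pool),
        variant=variant,
    )


def train_student(
    config: ModelConfig,
    train_docs: Sequence[EncodedDocument],
    soft_labels: SoftLabelSet,
    val_docs: Sequence[EncodedDocument],
    val_soft_labels: SoftLabelSet | None = None,
    monitor: str = "soft",
) -> ModelState:
    """Train the student MtCNN on ensemble soft labels.

    The training loop is identical to hard-label training; only the
    targets change.  Early stopping monitors the soft-target validation
    loss when ``monitor="soft"`` (requires ``val_soft_labels``), or the
    hard-label validation loss when ``monitor="hard"``.
    """
    train_ids = [d.id for d in train_docs]
    sl = soft_labels.subset(train_ids)
    val_targets = None
    if monitor == "soft":
        if val_soft_labels is None:
            raise ValueError('monitor="soft" requires validation soft labels')
        val_targets = val_soft_labels.subset([d.id for d in val_docs]).targets
    elif monitor != "hard":
        raise ValueError(f"unknown monitor {monitor!r}")
    return train_model(
        init_model(config),
        train_docs,
        val_docs,
        soft_targets=sl.targets,
        val_soft_targets=val_targets,
    )


def smooth_labels(label: int, alpha: float, K: int) -> np.ndarray:
    """Label smoothing: ``1 - alpha`` on the annotated class, ``alpha/(K-1)``
    on every other class."""
    if not (0.0 <= alpha < 1.0):
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if K < 2:
        raise ValueError("K must be >= 2")
    if not (0 <= label < K):
        raise ValueError(f"label {label} out of range for K={K}")
    y = np.full(K, alpha / (K - 1))
    y[label] = 1.0 - alpha
    return y


def smooth_label_targets(
    labels: Mapping[str, np.ndarray], schema, alpha: float
) -> dict[str, np.ndarray]:
    """Vectorized label smoothing over per-task hard-label arrays."""
    out = {}
    for name, K in schema:
        lab = np.asarray(labels[name])
        y = np.full((lab.shape[0], K), alpha / (K - 1), dtype=np.float32)
        y[np.arange(lab.shape[0]), lab] = 1.0 - alpha
        out[name] = y
    return out
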