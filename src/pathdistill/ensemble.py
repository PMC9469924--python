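"""Seed-diversified MtCNN ensembles: training, aggregation, vote profiles
and noise flagging.

The ensemble (teacher) is a pool of T identically configured MtCNNs
trained on the full training split with different initialization seeds —
no bagging.  Its decision for a document is the normalized sum of the
member softmax vectors, i.e. their arithmetic mean (a softmax-of-sum
variant is available for comparison).  Per-document vote profiles (how
the member argmax votes distribute over classes) drive two noise
analyses: unanimous wrong votes flag annotation errors, and near-equal
splits over 2-3 classes flag mixed-specimen documents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    ModelConfig,
    ModelState,
    PredictionSet,
    _softmax,
    forward,
    init_model,
    train_model,
)
from .io import EncodedDocument
from .types import TaskSchema


@dataclass
class EnsemblePool:
    """T trained members sharing schema, vocabulary and sequence length."""

    members: list[ModelState]
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seeds:
            self.seeds = [m.seed for m in self.members]
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("member seeds must be distinct")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def schema(self) -> TaskSchema:
        return self.members[0].config.schema

    def predict_members(
        self, docs: Sequence[EncodedDocument], batch_size: int = 256
    ) -> list[PredictionSet]:
        return [forward(m, docs, batch_size=batch_size) for m in self.members]

    def predict(
        self, docs: Sequence[EncodedDocument], variant: str = "mean"
    ) -> PredictionSet:
        return aggregate(self.predict_members(docs), variant=variant)


def train_pool(
    config: ModelConfig,
    train_docs: Sequence[EncodedDocument],
    val_docs: Sequence[EncodedDocument],
    T: int,
    base_seed: int,
) -> EnsemblePool:
    """Train ``T`` members on the full training split; member ``i`` is
    initialized with seed ``base_seed + i``.  Members are independent, so
    the result does not depend on execution order."""
    if T < 1:
        raise ValueError("ensemble size must be >= 1")
    members = []
    for i in range(T):
        cfg = ModelConfig(
            schema=config.schema,
            vocab_size=config.vocab_size,
            seq_len=config.seq_len,
            embedding_dim=config.embedding_dim,
            filter_widths=config.filter_widths,
            filters_per_width=config.filters_per_width,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            patience=config.patience,
            seed=base_seed + i,
        )
        members.append(train_model(init_model(cfg), train_docs, val_docs))
    return EnsemblePool(members=members)


def aggregate(
    member_predictions: Sequence[PredictionSet], variant: str = "mean"
) -> PredictionSet:
    """Combine member softmax outputs into the ensemble decision.

    ``variant="mean"`` (canonical): the arithmetic mean of the member
    probability vectors — summing then normalizing.  ``variant="softmax"``
    applies a softmax to the summed member outputs instead; it re-warps
    the probabilities and is provided only for comparison.
    """
    if not member_predictions:
        raise ValueError("no member predictions")
    first = member_predictions[0]
    for other in member_predictions[1:]:
        first.check_aligned(other)
    out: dict[str, np.ndarray] = {}
    for task in first.probs:
        stack = np.stack([m.probs[task] for m in member_predictions])
        total = stack.sum(axis=0)
        if variant == "mean":
            out[task] = total / len(member_predictions)
        elif variant == "softmax":
            out[task] = _softmax(total)
        else:
            raise ValueError(f"unknown aggregation variant {variant!r}")
    return PredictionSet(ids=list(first.ids), probs=out)


def majority_vote(counts: np.ndarray) -> int:
    """Class with the most member votes; ties break to the smallest index."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("vote counts must be nonnegative")
    return int(counts.argmax())


@dataclass
class VoteProfile:
    """Per-document, per-task tallies of member argmax votes."""

    ids: list[str]
    counts: dict[str, np.ndarray]  # task -> (N, K_t) integer vote counts
    T: int

    def agreement(self, task: str) -> np.ndarray:
        """Largest vote share per document: max_j count_j / T."""
        return self.counts[task].max(axis=1) / self.T

    def entropy(self, task: str) -> np.ndarray:
        """Shannon entropy (nats) of the vote distribution per document."""
        p = self.counts[task] / self.T
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, -p * np.log(p), 0.0)
        return terms.sum(axis=1)

    def winner(self, task: str) -> np.ndarray:
        """Majority-vote class per document (smallest index on ties)."""
        return self.counts[task].argmax(axis=1)


def vote_profile(member_predictions: Sequence[PredictionSet]) -> VoteProfile:
    """Tally each member's argmax prediction per document and task."""
    if not member_predictions:
        raise ValueError("no member predictions")
    first = member_predictions[0]
    for other in member_predictions[1:]:
        first.check_aligned(other)
    T = len(member_predictions)
    counts: dict[str, np.ndarray] = {}
    for task, p in first.probs.items():
        K = p.shape[1]
        votes = np.stack([m.probs[task].argmax(axis=1) for m in member_predictions])  # (T, N)
        c = np.zeros((p.shape[0], K), dtype=np.int64)
        for t in range(T):
            np.add.at(c, (np.arange(p.shape[0]), votes[t]), 1)
        counts[task] = c
    return VoteProfile(ids=list(first.ids), counts=counts, T=T)


@dataclass(frozen=True)
class NoiseFlag:
    id: str
    task: str
    predicted: int
    annotated: int
    agreement: float


def flag_label_noise(
    profile: VoteProfile,
    labels: Mapping[str, np.ndarray],
    min_agreement: float = 1.0,
) -> list[NoiseFlag]:
    """Flag documents whose ensemble vote is unanimous (agreement >=
    ``min_agreement``, default exactly 1.0) on a class different from the
    annotated label — the signature of an annotation error."""
    flags: list[NoiseFlag] = []
    for task, c in profile.counts.items():
        ann = np.asarray(labels[task])
        if ann.shape[0] != len(profile.ids):
            raise ValueError(f"task {task!r}: labels not aligned with profile")
        agree = c.max(axis=1) / profile.T
        win = c.argmax(axis=1)
        hit = (agree >= min_agreement) & (win != ann)
        for i in np.flatnonzero(hit):
            flags.append(
                NoiseFlag(
                    id=profile.ids[i],
                    task=task,
                    predicted=int(win[i]),
                    annotated=int(ann[i]),
                    agreement=float(agree[i]),
                )
            )
    return flags


@dataclass(frozen=True)
class SplitVoteFlag:
    id: str
    task: str
    k: int
    classes: tuple[int, ...]
    shares: tuple[float, ...]


def flag_split_votes(
    profile: VoteProfile, max_groups: int = 3, tolerance: float = 0.1
) -> list[SplitVoteFlag]:
    """Flag documents whose votes split almost equally over 2..max_groups
    classes — the signature of mixed-specimen data noise.

    A document is flagged for the smallest ``k`` such that its top-k vote
    shares each lie in ``[1/k - tol, 1/k + tol]`` and jointly cover at
    least ``1 - tol`` of the votes.
    """
    if not (0.0 < tolerance < 1.0 / max_groups):
        raise ValueError(
            f"tolerance must lie in (0, 1/{max_groups}), got {tolerance}"
        )
    flags: list[SplitVoteFlag] = []
    for task, c in profile.counts.items():
        shares = c / profile.T
        order = np.argsort(-shares, axis=1, kind="stable")
        sorted_shares = np.take_along_axis(shares, order, axis=1)
        for i in range(shares.shape[0]):
            for k in range(2, max_groups + 1):
                top = sorted_shares[i, :k]
                if (
                    (np.abs(top - 1.0 / k) <= tolerance + 1e-12).all()
                    and top.sum() >= 1.0 - tolerance - 1e-12
                ):
                    flags.append(
                        SplitVoteFlag(
                            id=profile.ids[i],
                            task=task,
                            k=k,
                            classes=tuple(int(j) for j in order[i, :k]),
                            shares=tuple(float(s) for s in top),
                        )
                    )
                    break
    return flags
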