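"""Corpus serialization, vocabulary construction and document encoding.

Corpora are stored as UTF-8 line-delimited JSON: the first line is a
header carrying the task schema, each following line one document with a
deterministic field order (id, registry, text, labels, truth).
Vocabularies serialize as TSV (token, index, frequency); index 0 is
reserved for padding and index 1 for out-of-vocabulary tokens.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .types import Document, LabeledCorpus, SchemaError, TaskSchema

PAD_INDEX = 0
UNK_INDEX = 1
_TOKEN_RE = re.compile(r"[a-z0-9]+")
_NUM_RE = re.compile(r"^[0-9]+$")
NUM_TOKEN = "NUM"


def tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphanumeric runs, collapse pure-numeric
    tokens to a single NUM symbol."""
    toks = _TOKEN_RE.findall(text.lower())
    return [NUM_TOKEN if _NUM_RE.match(t) else t for t in toks]


class CorpusFormatError(ValueError):
    """Malformed corpus file; message names the offending line."""


def write_corpus(corpus: LabeledCorpus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        header = {
            "schema": [[n, k] for n, k in corpus.schema],
            "registries": sorted(corpus.registries),
        }
        fh.write(json.dumps(header, sort_keys=False) + "\n")
        for d in corpus:
            rec = {
                "id": d.id,
                "registry": d.registry,
                "text": d.text,
                "labels": {n: d.labels[n] for n in corpus.schema.names},
            }
            if d.truth is not None:
                rec["truth"] = d.truth
            fh.write(json.dumps(rec, sort_keys=False) + "\n")


def read_corpus(path: str | Path) -> LabeledCorpus:
    path = Path(path)
    docs: list[Document] = []
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise CorpusFormatError(f"{path}: line 1: missing schema header")
        try:
            header = json.loads(header_line)
            schema = TaskSchema([(n, k) for n, k in header["schema"]])
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as e:
            raise CorpusFormatError(f"{path}: line 1: bad schema header ({e})") from e
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                doc = Document(
                    id=rec["id"],
                    registry=rec["registry"],
                    text=rec["text"],
                    labels={str(k): int(v) for k, v in rec["labels"].items()},
                    truth=rec.get("truth"),
                )
            except (json.JSONDecodeError, KeyError, TypeError) as e:
                raise CorpusFormatError(f"{path}: line {lineno}: malformed record ({e})") from e
            try:
                schema.validate_labels(doc.labels)
            except SchemaError as e:
                raise SchemaError(f"{path}: line {lineno}: {e}") from e
            docs.append(doc)
    return LabeledCorpus(schema, docs)


def write_schema(schema: TaskSchema, path: str | Path) -> None:
    """Write the task schema as a YAML list of {name, classes}."""
    data = {"tasks": [{"name": n, "classes": k} for n, k in schema]}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def read_schema(path: str | Path) -> TaskSchema:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return TaskSchema([(t["name"], t["classes"]) for t in data["tasks"]])


@dataclass(frozen=True)
class Vocabulary:
    """Token table with reserved padding (0) and unknown (1) indices.

    Tokens are ordered by descending corpus frequency with lexicographic
    tie-break, so vocabulary construction is deterministic.
    """

    index: dict[str, int]
    frequency: dict[str, int]
    min_freq: int
    max_size: int | None

    def __len__(self) -> int:
        return len(self.index) + 2  # + PAD, UNK

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def lookup(self, token: str) -> int:
        return self.index.get(token, UNK_INDEX)

    def save(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for tok, idx in sorted(self.index.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok}\t{idx}\t{self.frequency[tok]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        index: dict[str, int] = {}
        freq: dict[str, int] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            tok, idx, f = line.split("\t")
            index[tok] = int(idx)
            freq[tok] = int(f)
        return cls(index=index, frequency=freq, min_freq=1, max_size=None)


def build_vocab(
    corpus: LabeledCorpus | Iterable[Document],
    min_freq: int = 1,
    max_size: int | None = None,
) -> Vocabulary:
    """Count tokens over the corpus and keep the ``max_size`` most frequent
    with frequency >= ``min_freq``; frequency ties break lexicographically."""
    counts: dict[str, int] = {}
    for doc in corpus:
        for tok in tokenize(doc.text):
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(
        (t for t, c in counts.items() if c >= min_freq),
        key=lambda t: (-counts[t], t),
    )
    if max_size is not None:
        kept = kept[:max_size]
    index = {tok: i + 2 for i, tok in enumerate(kept)}
    return Vocabulary(
        index=index,
        frequency={t: counts[t] for t in kept},
        min_freq=min_freq,
        max_size=max_size,
    )


@dataclass(frozen=True)
class EncodedDocument:
    """A document rendered as a fixed-length token-index sequence."""

    id: str
    registry: str
    token_ids: np.ndarray  # shape (L,), int32
    labels: dict[str, int]


def encode_document(doc: Document, vocab: Vocabulary, seq_len: int) -> EncodedDocument:
    toks = tokenize(doc.text)[:seq_len]
    ids = np.full(seq_len, PAD_INDEX, dtype=np.int32)
    for i, t in enumerate(toks):
        ids[i] = vocab.lookup(t)
    return EncodedDocument(id=doc.id, registry=doc.registry, token_ids=ids, labels=doc.labels)


def encode_corpus(
    corpus: LabeledCorpus | Sequence[Document], vocab: Vocabulary, seq_len: int
) -> list[EncodedDocument]:
    """Encode every document: head-truncated to ``seq_len``, right-padded
    with 0, out-of-vocabulary tokens mapped to 1."""
    if seq_len < 1:
        raise ValueError(f"sequence length must be >= 1, got {seq_len}")
    return [encode_document(d, vocab, seq_len) for d in corpus]


def stack_encoded(
    docs: Sequence[EncodedDocument], schema: TaskSchema
) -> tuple[list[str], np.ndarray, dict[str, np.ndarray]]:
    """Stack encoded documents into (ids, token matrix, per-task label arrays)."""
    ids = [d.id for d in docs]
    X = np.stack([d.token_ids for d in docs]) if docs else np.zeros((0, 0), dtype=np.int32)
    y = {
        name: np.array([d.labels[name] for d in docs], dtype=np.int64)
        for name in schema.names
    }
    return ids, X, y
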