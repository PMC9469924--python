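"""Core domain containers shared across the pipeline.

A corpus is a flat list of documents, each carrying free text, a registry
tag (the population-based cancer registry the report came from) and one
hard label per coding task.  The five real-world tasks are site, subsite,
laterality, histology and behavior; the containers are generic over any
ordered task schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence


class SchemaError(ValueError):
    """A label or task violates the task schema."""


@dataclass(frozen=True)
class TaskSchema:
    """Ordered list of classification tasks and their class counts.

    Parameters
    ----------
    tasks : sequence of (name, n_classes)
        Order is significant and shared by every label container built
        against this schema.  Class counts must be >= 2.
    """

    tasks: tuple[tuple[str, int], ...]

    def __init__(self, tasks: Sequence[tuple[str, int]]):
        tasks = tuple((str(n), int(k)) for n, k in tasks)
        names = [n for n, _ in tasks]
        if len(set(names)) != len(names):
            raise SchemaError(f"duplicate task names in {names}")
        for name, k in tasks:
            if k < 2:
                raise SchemaError(f"task {name!r} has {k} classes; need >= 2")
        object.__setattr__(self, "tasks", tasks)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.tasks)

    @property
    def n_classes(self) -> dict[str, int]:
        return dict(self.tasks)

    def n_classes_of(self, task: str) -> int:
        for n, k in self.tasks:
            if n == task:
                return k
        raise SchemaError(f"unknown task {task!r}")

    def __len__(self) -> int:
        return len(self.tasks)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.tasks)

    def validate_labels(self, labels: Mapping[str, int]) -> None:
        if set(labels) != set(self.names):
            raise SchemaError(
                f"labels {sorted(labels)} do not match tasks {sorted(self.names)}"
            )
        for name, k in self.tasks:
            j = labels[name]
            if not (0 <= j < k):
                raise SchemaError(
                    f"label {j} out of range for task {name!r} with {k} classes"
                )

    @classmethod
    def reference_profile(cls) -> "TaskSchema":
        """The five coding tasks of the real registry problem."""
        return cls(
            [
                ("site", 70),
                ("subsite", 326),
                ("laterality", 7),
                ("histology", 639),
                ("behavior", 4),
            ]
        )


@dataclass(frozen=True)
class Document:
    """One pathology report: text, registry tag and per-task hard labels.

    ``truth`` is generator-only metadata present iff the document is
    synthetic: the pre-noise class per task, mixing classes/weights for
    mixed-specimen documents and the label-noise flag.
    """

    id: str
    registry: str
    text: str
    labels: dict[str, int]
    truth: dict | None = None

    def with_labels(self, labels: Mapping[str, int]) -> "Document":
        return replace(self, labels=dict(labels))


@dataclass
class LabeledCorpus:
    """A schema plus a sequence of labeled documents."""

    schema: TaskSchema
    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate document ids")
        for d in self.documents:
            self.schema.validate_labels(d.labels)

    @property
    def registries(self) -> set[str]:
        return {d.registry for d in self.documents}

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def subset(self, ids: Sequence[str]) -> "LabeledCorpus":
        wanted = set(ids)
        return LabeledCorpus(
            self.schema, [d for d in self.documents if d.id in wanted]
        )

    def labels_array(self, task: str) -> list[int]:
        return [d.labels[task] for d in self.documents]
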