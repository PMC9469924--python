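"""Synthetic multitask pathology-report corpus generator.

Real registry corpora are restricted, so every downstream stage is
exercised on generated corpora that reproduce the *statistical* structure
of the problem rather than clinical language:

* extreme class imbalance (truncated power law over class ranks),
* mixed-specimen data noise (documents whose token stream blends the
  vocabularies of 2-3 classes with Dirichlet weights),
* annotation label noise (a fraction of documents has one task's label
  swapped for a lexically confusable class),
* cross-task label coupling (each "subsite" class belongs to one "site"
  class, and the remaining tasks are drawn conditionally on site),
* per-registry distribution shift, so leave-one-registry-out evaluation
  degrades out of distribution.

Every class owns a token vocabulary that overlaps only with its ring
neighbours; classes are therefore lexically separable by construction,
which is what makes noise-recovery experiments well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .types import Document, LabeledCorpus, TaskSchema


class GenerationError(RuntimeError):
    """Raised when a generator configuration cannot produce a valid corpus."""


def sample_label_distribution(K: int, s: float, seed: int) -> np.ndarray:
    """Power-law class distribution: rank ``r`` gets mass proportional to
    ``r**(-s)``, and ranks are assigned to class indices by a seeded
    permutation.

    ``s = 0`` gives the uniform distribution; larger ``s`` concentrates
    mass on a few head classes, mimicking the extreme imbalance of
    subsite/histology coding.
    """
    if K < 2:
        raise ValueError(f"need at least 2 classes, got K={K}")
    if s < 0:
        raise ValueError(f"imbalance exponent must be >= 0, got s={s}")
    ranks = np.arange(1, K + 1, dtype=float)
    ranked = ranks ** (-float(s))
    ranked /= ranked.sum()
    perm = np.random.default_rng(seed).permutation(K)
    p = np.empty(K)
    p[perm] = ranked
    return p


def top_mass(K: int, s: float, n_top: int = 2) -> float:
    """Total probability of the ``n_top`` head classes under the power law."""
    ranks = np.arange(1, K + 1, dtype=float)
    w = ranks ** (-float(s))
    return float(w[:n_top].sum() / w.sum())


def calibrate_imbalance(K: int, target: float, n_top: int = 2) -> float:
    """Find the exponent ``s`` whose ``n_top`` head classes carry ``target``
    mass, by bisection (the head mass is strictly increasing in ``s``).
    """
    lo_mass = top_mass(K, 0.0, n_top)
    if not (lo_mass < target < 1.0):
        raise ValueError(
            f"target head mass {target} unreachable for K={K} (uniform gives {lo_mass:.4f})"
        )
    return float(brentq(lambda s: top_mass(K, s, n_top) - target, 0.0, 64.0, xtol=1e-10))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus generator.

    Parameters
    ----------
    schema : TaskSchema
        Tasks and class counts.  Task 0 plays the "site" role; task 1 (if
        present) plays "subsite" and is partitioned among site classes;
        later tasks are drawn conditionally on site.
    docs_per_registry : mapping registry tag -> document count.
    imbalance : per-task power-law exponent ``s >= 0`` (scalar applies to
        all tasks).
    mix_rate : fraction of documents blending the vocabularies of 2-3
        classes (mixed-specimen noise).
    label_noise_rate : fraction of documents whose label on one task is
        swapped to a confusable class after generation.
    tokens_per_doc : inclusive (min, max) document length in tokens.
    class_vocab_size : tokens owned by each (task, class); a fifth of them
        are shared with each ring neighbour, so adjacent classes are
        confusable.
    background_vocab_size : size of the shared topic-free vocabulary.
    background_rate : per-token probability of drawing a background token.
    registry_shift : in [0, 1]; strength of per-registry tilts of the class
        and background-token distributions.
    seed : master seed; identical config + seed gives a byte-identical
        corpus.
    """

    schema: TaskSchema
    docs_per_registry: Mapping[str, int]
    imbalance: float | Mapping[str, float] = 1.0
    mix_rate: float = 0.0
    label_noise_rate: float = 0.0
    tokens_per_doc: tuple[int, int] = (20, 60)
    class_vocab_size: int = 20
    background_vocab_size: int = 200
    background_rate: float = 0.3
    registry_shift: float = 0.0
    coupling_strength: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in [
            ("mix_rate", self.mix_rate),
            ("label_noise_rate", self.label_noise_rate),
            ("background_rate", self.background_rate),
            ("registry_shift", self.registry_shift),
        ]:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.tokens_per_doc
        if lo > hi or lo < 1:
            raise ValueError(f"bad tokens_per_doc range {self.tokens_per_doc}")
        for t in self.schema.names:
            if self.imbalance_of(t) < 0:
                raise ValueError("imbalance exponents must be >= 0")
        if any(n < 0 for n in self.docs_per_registry.values()):
            raise ValueError("document counts must be >= 0")

    def imbalance_of(self, task: str) -> float:
        if isinstance(self.imbalance, Mapping):
            return float(self.imbalance[task])
        return float(self.imbalance)


def _class_vocab(task_idx: int, j: int, K: int, size: int) -> list[str]:
    """Token set of class ``j``: unique tokens plus tokens shared with the
    ring neighbours ``j-1`` and ``j+1`` (the confusable classes)."""
    n_shared = max(1, size // 5)
    n_unique = max(0, size - 2 * n_shared)
    toks = [f"t{task_idx}c{j}w{i}" for i in range(n_unique)]
    left, right = (j - 1) % K, j
    toks += [f"t{task_idx}sh{left}w{i}" for i in range(n_shared)]
    toks += [f"t{task_idx}sh{right}w{i}" for i in range(n_shared)]
    return toks


def confusable_classes(j: int, K: int) -> tuple[int, ...]:
    """Classes sharing vocabulary overlap with ``j`` (its ring neighbours)."""
    left, right = (j - 1) % K, (j + 1) % K
    return (left,) if left == right else (left, right)


class _World:
    """Precomputed vocabularies and (registry, site)-conditional label
    distributions for one GeneratorConfig."""

    def __init__(self, config: GeneratorConfig):
        self.config = config
        schema = config.schema
        names = schema.names
        ss = np.random.SeedSequence(config.seed)
        # independent deterministic streams: base dists, registry tilts,
        # site-coupling tilts, document sampling, label noise
        s_base, s_reg, s_coup, self.s_docs, self.s_noise = ss.spawn(5)

        self.vocab: dict[tuple[str, int], list[str]] = {}
        for ti, (name, K) in enumerate(schema):
            seen: dict[frozenset, int] = {}
            for j in range(K):
                toks = _class_vocab(ti, j, K, config.class_vocab_size)
                key = frozenset(toks)
                if key in seen:
                    raise GenerationError(
                        f"classes {seen[key]} and {j} of task {name!r} were "
                        "assigned identical token sets; increase class_vocab_size"
                    )
                seen[key] = j
                self.vocab[(name, j)] = toks
        self.background = [f"bgw{i}" for i in range(config.background_vocab_size)]

        base_rng = np.random.default_rng(s_base)
        self.base: dict[str, np.ndarray] = {
            name: sample_label_distribution(
                K, config.imbalance_of(name), int(base_rng.integers(2**31))
            )
            for name, K in schema
        }

        # subsite -> site partition (round robin)
        if len(names) >= 2:
            K0 = schema.n_classes_of(names[0])
            K1 = schema.n_classes_of(names[1])
            self.site_of_subsite = np.arange(K1) % K0
        else:
            self.site_of_subsite = None

        # per-registry tilts of every task distribution and of background
        reg_rng = np.random.default_rng(s_reg)
        self.registry_dists: dict[str, dict[str, np.ndarray]] = {}
        self.registry_bg: dict[str, np.ndarray] = {}
        for reg in sorted(config.docs_per_registry):
            dists = {}
            for name, K in schema:
                z = reg_rng.standard_normal(K)
                p = self.base[name] * np.exp(config.registry_shift * z)
                dists[name] = p / p.sum()
            self.registry_dists[reg] = dists
            zb = reg_rng.standard_normal(len(self.background))
            pb = np.exp(config.registry_shift * zb)
            self.registry_bg[reg] = pb / pb.sum()

        # site-conditional tilts for tasks beyond site/subsite
        coup_rng = np.random.default_rng(s_coup)
        self.coupling: dict[str, np.ndarray] = {}
        if len(names) >= 3:
            K0 = schema.n_classes_of(names[0])
            for name in names[2:]:
                K = schema.n_classes_of(name)
                self.coupling[name] = coup_rng.standard_normal((K0, K))

    def sample_label_tuple(self, rng: np.random.Generator, registry: str) -> dict[str, int]:
        """Draw one coherent per-task label tuple for a registry."""
        schema = self.config.schema
        names = schema.names
        dists = self.registry_dists[registry]
        labels: dict[str, int] = {}
        site = int(rng.choice(len(dists[names[0]]), p=dists[names[0]]))
        labels[names[0]] = site
        if len(names) >= 2:
            p = dists[names[1]].copy()
            admissible = self.site_of_subsite == site
            if admissible.any():
                p = np.where(admissible, p, 0.0)
            p /= p.sum()
            labels[names[1]] = int(rng.choice(len(p), p=p))
        for name in names[2:]:
            p = dists[name] * np.exp(
                self.config.coupling_strength * self.coupling[name][site]
            )
            p /= p.sum()
            labels[name] = int(rng.choice(len(p), p=p))
        return labels


def generate_corpus(config: GeneratorConfig) -> LabeledCorpus:
    """Generate a labeled corpus under ``config``.

    Each document's token stream mixes background tokens with tokens drawn
    from the class vocabularies of its label tuple; a mixed-specimen
    document carries 2-3 label tuples with Dirichlet weights and its hard
    labels come from the heaviest component.  Label noise, if requested,
    is injected afterwards via :func:`inject_label_noise`.
    """
    world = _World(config)
    schema = config.schema
    names = schema.names
    rng = np.random.default_rng(world.s_docs)
    lo, hi = config.tokens_per_doc
    docs: list[Document] = []
    for registry in sorted(config.docs_per_registry):
        bg_p = world.registry_bg[registry]
        for i in range(int(config.docs_per_registry[registry])):
            mixed = rng.random() < config.mix_rate
            n_comp = int(rng.integers(2, 4)) if mixed else 1
            components = [world.sample_label_tuple(rng, registry) for _ in range(n_comp)]
            weights = (
                rng.dirichlet(np.ones(n_comp)) if n_comp > 1 else np.ones(1)
            )
            primary = int(np.argmax(weights))
            labels = dict(components[primary])

            n_tok = int(rng.integers(lo, hi + 1))
            toks: list[str] = []
            for _ in range(n_tok):
                if rng.random() < config.background_rate:
                    toks.append(world.background[int(rng.choice(len(bg_p), p=bg_p))])
                else:
                    c = int(rng.choice(n_comp, p=weights)) if n_comp > 1 else 0
                    task = names[int(rng.integers(len(names)))]
                    vocab = world.vocab[(task, components[c][task])]
                    toks.append(vocab[int(rng.integers(len(vocab)))])

            truth = {
                "true_labels": dict(labels),
                "mixing": (
                    {
                        "components": [dict(c) for c in components],
                        "weights": [float(w) for w in weights],
                    }
                    if n_comp > 1
                    else None
                ),
                "label_noise": False,
            }
            docs.append(
                Document(
                    id=f"{registry}-{i:06d}",
                    registry=registry,
                    text=" ".join(toks),
                    labels=labels,
                    truth=truth,
                )
            )
    corpus = LabeledCorpus(schema, docs)
    if config.label_noise_rate > 0:
        corpus = inject_label_noise(
            corpus,
            config.label_noise_rate,
            int(np.random.default_rng(world.s_noise).integers(2**31)),
        )
    return corpus


def inject_label_noise(corpus: LabeledCorpus, rho: float, seed: int) -> LabeledCorpus:
    """Corrupt a Bernoulli(``rho``) fraction of documents: one task's label
    (chosen uniformly) is replaced by a confusable class, i.e. a ring
    neighbour sharing vocabulary overlap with the true class.

    The returned corpus carries ``truth["label_noise"] = True`` and the
    original labels in ``truth["true_labels"]`` for every corrupted
    document, so noise recovery is exactly measurable.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"noise rate must be in [0, 1], got {rho}")
    rng = np.random.default_rng(seed)
    names = corpus.schema.names
    out: list[Document] = []
    for doc in corpus:
        if rho > 0 and rng.random() < rho:
            task = names[int(rng.integers(len(names)))]
            K = corpus.schema.n_classes_of(task)
            true_j = doc.labels[task]
            options = confusable_classes(true_j, K)
            new_j = int(options[int(rng.integers(len(options)))])
            labels = dict(doc.labels)
            labels[task] = new_j
            truth = dict(doc.truth or {"true_labels": dict(doc.labels), "mixing": None})
            truth["label_noise"] = True
            truth["noised_task"] = task
            out.append(replace(doc, labels=labels, truth=truth))
        else:
            out.append(doc)
    return LabeledCorpus(corpus.schema, out)
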