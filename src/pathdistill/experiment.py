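"""Leave-one-registry-out deployment experiment.

End-to-end pipeline: generate (or load) a corpus, hold out one registry
as the out-of-distribution test set, train the hard-label baseline MtCNN,
the seed-diversified ensemble and the distilled student, calibrate
per-task softmax thresholds to the target accuracy on validation, apply
them to the held-out registry and report retention proportions, retained
accuracy and the overconfidence / noise diagnostics in one comparison
report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .abstention import (
    RetentionReport,
    SizeCurve,
    ThresholdTable,
    apply_abstention,
    calibrate_thresholds,
    count_overconfident_wrong,
    ensemble_size_curve,
    wrong_confidence_histogram,
)
from .distill import derive_soft_labels, smooth_label_targets, train_student
from .ensemble import (
    EnsemblePool,
    NoiseFlag,
    SplitVoteFlag,
    aggregate,
    flag_label_noise,
    flag_split_votes,
    train_pool,
    vote_profile,
)
from .io import build_vocab, encode_corpus, stack_encoded, write_corpus
from .model import (
    ModelConfig,
    ModelState,
    PredictionSet,
    forward,
    init_model,
    save_checkpoint,
    train_model,
)
from .synthetic import GeneratorConfig, generate_corpus
from .types import LabeledCorpus, TaskSchema

logger = logging.getLogger("pathdistill")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def split_leave_one_registry_out(
    corpus: LabeledCorpus,
    held_out: str,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[LabeledCorpus, LabeledCorpus, LabeledCorpus]:
    """Partition a corpus for deployment evaluation.

    The held-out registry's documents form the test set; the remaining
    documents are shuffled by ``seed`` and split into train/validation by
    ``val_fraction``.  The three sets are disjoint and exhaustive.
    """
    if held_out not in corpus.registries:
        raise ValueError(f"unknown registry {held_out!r}; have {sorted(corpus.registries)}")
    if not (0.0 < val_fraction < 1.0):
        raise ValueError("validation fraction must be in (0, 1)")
    test_docs = [d for d in corpus if d.registry == held_out]
    rest = [d for d in corpus if d.registry != held_out]
    order = np.random.default_rng(seed).permutation(len(rest))
    n_val = int(round(val_fraction * len(rest)))
    val_docs = [rest[i] for i in order[:n_val]]
    train_docs = [rest[i] for i in order[n_val:]]
    mk = lambda docs: LabeledCorpus(corpus.schema, docs)
    return mk(train_docs), mk(val_docs), mk(test_docs)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of one leave-one-registry-out run."""

    generator: GeneratorConfig
    held_out: str
    pool_size: int = 20
    val_fraction: float = 0.1
    seq_len: int = 64
    embedding_dim: int = 32
    filter_widths: tuple[int, ...] = (3, 4, 5)
    filters_per_width: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 20
    patience: int = 5
    min_freq: int = 1
    max_vocab: int | None = None
    target_accuracy: float = 0.97
    overconfidence_cutoff: float = 0.97
    histogram_edges: tuple[float, ...] = (0.0, 0.5, 0.6, 0.7, 0.8, 0.9, 0.97, 1.0)
    curve_sizes: tuple[int, ...] = (1, 2, 5, 10, 20)
    curve_replicates: int = 50
    include_smoothing_baseline: bool = False
    seed: int = 0
    out_dir: str | None = None

    def model_config(self, vocab_size: int, seed: int) -> ModelConfig:
        return ModelConfig(
            schema=self.generator.schema,
            vocab_size=vocab_size,
            seq_len=self.seq_len,
            embedding_dim=self.embedding_dim,
            filter_widths=self.filter_widths,
            filters_per_width=self.filters_per_width,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=seed,
        )

    def fingerprint(self) -> str:
        blob = json.dumps(
            {
                "schema": list(self.generator.schema.tasks),
                "docs": dict(self.generator.docs_per_registry),
                "mix": self.generator.mix_rate,
                "noise": self.generator.label_noise_rate,
                "shift": self.generator.registry_shift,
                "held_out": self.held_out,
                "T": self.pool_size,
                "seed": self.seed,
                "model": [
                    self.seq_len,
                    self.embedding_dim,
                    list(self.filter_widths),
                    self.filters_per_width,
                    self.max_epochs,
                    self.patience,
                ],
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ComparisonReport:
    """Tables comparing baseline, student and ensemble after abstention."""

    retention: dict[str, RetentionReport]
    overconfident_wrong: dict[str, dict[str, int]]
    histograms: dict[str, dict[str, list[int]]]
    noise_flags: list[NoiseFlag]
    split_flags: list[SplitVoteFlag]
    size_curve: SizeCurve | None
    provenance: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for model, rep in self.retention.items():
            for task, r in rep.tasks.items():
                rows.append(
                    {
                        "model": model,
                        "task": task,
                        "threshold": r.threshold,
                        "rp_percent": r.rp,
                        "accuracy": r.accuracy,
                        "retained": r.retained,
                        "total": r.total,
                        "overconf_wrong": self.overconfident_wrong[model][task],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_dataframe()
        lines = [
            "Leave-one-registry-out comparison",
            "=" * 48,
            df.to_string(
                index=False,
                float_format=lambda v: f"{v:.2f}",
                columns=["model", "task", "rp_percent", "accuracy", "overconf_wrong"],
            ),
            f"label-noise flags: {len(self.noise_flags)}",
            f"split-vote flags:  {len(self.split_flags)}",
        ]
        return "\n".join(lines)


def _hard_labels(docs, schema: TaskSchema) -> dict[str, np.ndarray]:
    _, _, y = stack_encoded(docs, schema)
    return y


def run_experiment(config: ExperimentConfig) -> ComparisonReport:
    """Execute the full pipeline (generate -> split -> baseline -> pool ->
    soft labels -> student -> calibrate -> abstain -> analyses).

    Deterministic for a fixed config + seed.  When ``out_dir`` is set,
    every intermediate artifact (corpus, vocabulary, checkpoints,
    thresholds, tables) is persisted as it is produced.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        logger.info("stage %s", name)
        return time.time()

    stage = "generate"
    try:
        t0 = _stage(stage)
        corpus = generate_corpus(config.generator)
        if out:
            write_corpus(corpus, out / "corpus.jsonl")

        stage = "split"
        train_c, val_c, test_c = split_leave_one_registry_out(
            corpus, config.held_out, config.val_fraction, config.seed
        )
        schema = corpus.schema

        stage = "encode"
        vocab = build_vocab(train_c, min_freq=config.min_freq, max_size=config.max_vocab)
        if out:
            vocab.save(out / "vocab.tsv")
        enc_train = encode_corpus(train_c, vocab, config.seq_len)
        enc_val = encode_corpus(val_c, vocab, config.seq_len)
        enc_test = encode_corpus(test_c, vocab, config.seq_len)
        y_val = _hard_labels(enc_val, schema)
        y_test = _hard_labels(enc_test, schema)

        stage = "train-baseline"
        baseline = train_model(
            init_model(config.model_config(len(vocab), config.seed)), enc_train, enc_val
        )
        if out:
            save_checkpoint(baseline, out / "baseline.npz")

        stage = "train-pool"
        pool = train_pool(
            config.model_config(len(vocab), 0),
            enc_train,
            enc_val,
            T=config.pool_size,
            base_seed=config.seed + 1,
        )
        if out:
            pool_dir = out / "pool"
            pool_dir.mkdir(exist_ok=True)
            manifest = []
            for i, m in enumerate(pool.members):
                p = pool_dir / f"member_{i:04d}.npz"
                save_checkpoint(m, p)
                manifest.append({"path": p.name, "seed": m.seed})
            (pool_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest))

        stage = "distill"
        soft_train = derive_soft_labels(pool, enc_train)
        soft_val = derive_soft_labels(pool, enc_val)
        student = train_student(
            config.model_config(len(vocab), config.seed + config.pool_size + 1),
            enc_train,
            soft_train,
            enc_val,
            val_soft_labels=soft_val,
        )
        if out:
            save_checkpoint(student, out / "student.npz")

        smoothing = None
        if config.include_smoothing_baseline:
            # contrast arm: label smoothing with alpha matched to the mean
            # confidence of the ensemble soft labels
            stage = "train-smoothing"
            mean_conf = float(
                np.mean([soft_train.targets[t].max(axis=1).mean() for t in schema.names])
            )
            alpha = min(max(1.0 - mean_conf, 0.0), 0.99)
            y_train_hard = _hard_labels(enc_train, schema)
            sm_train = smooth_label_targets(y_train_hard, schema, alpha)
            sm_val = smooth_label_targets(y_val, schema, alpha)
            smoothing = train_model(
                init_model(
                    config.model_config(len(vocab), config.seed + config.pool_size + 2)
                ),
                enc_train,
                enc_val,
                soft_targets=sm_train,
                val_soft_targets=sm_val,
            )
            if out:
                save_checkpoint(smoothing, out / "smoothing.npz")

        stage = "predict"
        member_val = pool.predict_members(enc_val)
        member_test = pool.predict_members(enc_test)
        preds_val = {
            "baseline": forward(baseline, enc_val),
            "student": forward(student, enc_val),
            "ensemble": aggregate(member_val),
        }
        preds_test = {
            "baseline": forward(baseline, enc_test),
            "student": forward(student, enc_test),
            "ensemble": aggregate(member_test),
        }
        if smoothing is not None:
            preds_val["smoothing"] = forward(smoothing, enc_val)
            preds_test["smoothing"] = forward(smoothing, enc_test)

        stage = "calibrate"
        thresholds: dict[str, ThresholdTable] = {
            model: calibrate_thresholds(pv, y_val, config.target_accuracy)
            for model, pv in preds_val.items()
        }
        if out:
            for model, tt in thresholds.items():
                (out / f"thresholds_{model}.yaml").write_text(
                    yaml.safe_dump({"target": tt.target, "thresholds": tt.thresholds})
                )

        stage = "evaluate"
        retention = {
            model: apply_abstention(preds_test[model], y_test, thresholds[model])
            for model in preds_test
        }
        overconf = {
            model: {
                task: count_overconfident_wrong(
                    preds_test[model], y_test, task, config.overconfidence_cutoff
                )
                for task in schema.names
            }
            for model in preds_test
        }
        hists = {
            model: {
                task: wrong_confidence_histogram(
                    preds_test[model], y_test, task, config.histogram_edges
                ).tolist()
                for task in schema.names
            }
            for model in preds_test
        }

        stage = "analyze-noise"
        member_train = pool.predict_members(enc_train)
        profile = vote_profile(member_train)
        y_train = _hard_labels(enc_train, schema)
        noise_flags = flag_label_noise(profile, y_train)
        split_flags = flag_split_votes(profile)

        stage = "size-curve"
        curve = None
        sizes = [m for m in config.curve_sizes if m <= len(pool)]
        if sizes:
            curve = ensemble_size_curve(
                member_test,
                y_test,
                sizes,
                replicates=config.curve_replicates,
                seed=config.seed,
            )

        report = ComparisonReport(
            retention=retention,
            overconfident_wrong=overconf,
            histograms=hists,
            noise_flags=noise_flags,
            split_flags=split_flags,
            size_curve=curve,
            provenance={
                "config_hash": config.fingerprint(),
                "seed": config.seed,
                "pool_size": config.pool_size,
                "held_out": config.held_out,
                "vocab_size": len(vocab),
                "splits": {
                    "train": len(train_c),
                    "val": len(val_c),
                    "test": len(test_c),
                },
                "wall_time_s": round(time.time() - t0, 2),
            },
        )
        if out:
            report.to_dataframe().to_csv(out / "comparison.tsv", sep="\t", index=False)
            _write_flags(out, noise_flags, split_flags)
            if curve:
                _write_curve(out / "size_curve.tsv", curve)
            (out / "report.json").write_text(
                json.dumps(_report_json(report), indent=2)
            )
        return report
    except Exception as e:  # noqa: BLE001 - surface the failing stage
        if isinstance(e, StageError):
            raise
        raise StageError(f"stage {stage!r} failed: {e}") from e


def _write_flags(out: Path, noise_flags, split_flags) -> None:
    with (out / "label_noise_flags.tsv").open("w") as fh:
        fh.write("id\ttask\tpredicted\tannotated\tagreement\n")
        for f in noise_flags:
            fh.write(f"{f.id}\t{f.task}\t{f.predicted}\t{f.annotated}\t{f.agreement}\n")
    with (out / "split_vote_flags.tsv").open("w") as fh:
        fh.write("id\ttask\tk\tclasses\tshares\n")
        for f in split_flags:
            cls = ",".join(map(str, f.classes))
            sh = ",".join(f"{s:.3f}" for s in f.shares)
            fh.write(f"{f.id}\t{f.task}\t{f.k}\t{cls}\t{sh}\n")


def _write_curve(path: Path, curve: SizeCurve) -> None:
    with path.open("w") as fh:
        fh.write("task\tsize\tmean\tstd\n")
        for task in curve.means:
            for m, mean, std in zip(curve.sizes, curve.means[task], curve.stds[task]):
                fh.write(f"{task}\t{m}\t{mean}\t{std}\n")


def _report_json(report: ComparisonReport) -> dict:
    return {
        "retention": {
            model: rep.to_rows() for model, rep in report.retention.items()
        },
        "overconfident_wrong": report.overconfident_wrong,
        "histograms": report.histograms,
        "n_noise_flags": len(report.noise_flags),
        "n_split_flags": len(report.split_flags),
        "size_curve": (
            {
                "sizes": report.size_curve.sizes,
                "means": report.size_curve.means,
            }
            if report.size_curve
            else None
        ),
        "provenance": report.provenance,
    }


def save_predictions(pset: PredictionSet, prefix: str | Path) -> None:
    """Persist a prediction matrix as .npz (per-task arrays) + TSV id index."""
    prefix = Path(prefix)
    np.savez(prefix.with_suffix(".npz"), **pset.probs)
    with prefix.with_suffix(".ids.tsv").open("w") as fh:
        for i, doc_id in enumerate(pset.ids):
            fh.write(f"{doc_id}\t{i}\n")


def load_predictions(prefix: str | Path) -> PredictionSet:
    prefix = Path(prefix)
    with np.load(prefix.with_suffix(".npz")) as z:
        probs = {k: z[k] for k in z.files}
    ids = [
        line.split("\t")[0]
        for line in prefix.with_suffix(".ids.tsv").read_text().splitlines()
    ]
    return PredictionSet(ids=ids, probs=probs)
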