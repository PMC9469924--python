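"""Shared fixtures: small deterministic corpora and the seeded desk
benchmark (3 replicates of the full leave-one-registry-out pipeline on
synthetic data) used by the stochastic acceptance-style tests."""

from __future__ import annotations

import numpy as np
import pytest

from pathdistill import (
    ExperimentConfig,
    GeneratorConfig,
    TaskSchema,
    generate_corpus,
    run_experiment,
)

DESK_SCHEMA = TaskSchema([("site", 10), ("subsite", 25), ("behavior", 4)])


def desk_generator(seed: int, mix_rate: float = 0.2, noise: float = 0.05,
                   docs_per_registry: int = 800) -> GeneratorConfig:
    """Study conditions of the desk benchmark: 3 tasks, 6 registries,
    mixed-specimen rate 0.2, label-noise rate 0.05, registry shift 0.3."""
    return GeneratorConfig(
        schema=DESK_SCHEMA,
        docs_per_registry={f"R{i}": docs_per_registry for i in range(1, 7)},
        imbalance=0.8,
        mix_rate=mix_rate,
        label_noise_rate=noise,
        registry_shift=0.3,
        seed=100 + seed,
    )


def desk_experiment(seed: int, **overrides) -> ExperimentConfig:
    kw = dict(
        generator=desk_generator(seed),
        held_out="R4",
        pool_size=20,
        val_fraction=0.1,
        seq_len=48,
        embedding_dim=16,
        filters_per_width=16,
        learning_rate=2e-3,
        batch_size=64,
        max_epochs=15,
        patience=3,
        curve_sizes=(1, 2, 5, 10, 20),
        curve_replicates=50,
        seed=1000 * seed,
    )
    kw.update(overrides)
    return ExperimentConfig(**kw)


@pytest.fixture(scope="session")
def desk_benchmark():
    """Three seeded replicates of the full pipeline (T=20, ~4800 docs)."""
    out = {}
    for rep in range(3):
        cfg = desk_experiment(rep)
        out[rep] = {
            "config": cfg,
            "report": run_experiment(cfg),
            "corpus": generate_corpus(cfg.generator),  # for truth lookup
        }
    return out


@pytest.fixture(scope="session")
def noise_benchmark():
    """Separable corpus (mix 0) with 10% injected label noise and a
    T=20 pool, for unanimity-based noise recovery."""
    from pathdistill import (
        build_vocab,
        encode_corpus,
        flag_label_noise,
        split_leave_one_registry_out,
        stack_encoded,
        train_pool,
        vote_profile,
    )

    gen = desk_generator(seed=50, mix_rate=0.0, noise=0.10, docs_per_registry=500)
    corpus = generate_corpus(gen)
    train_c, val_c, _ = split_leave_one_registry_out(corpus, "R4", 0.1, 7)
    vocab = build_vocab(train_c)
    enc_train = encode_corpus(train_c, vocab, 48)
    enc_val = encode_corpus(val_c, vocab, 48)
    from pathdistill import ModelConfig

    cfg = ModelConfig(
        schema=gen.schema,
        vocab_size=len(vocab),
        seq_len=48,
        embedding_dim=16,
        filters_per_width=16,
        learning_rate=2e-3,
        batch_size=64,
        max_epochs=15,
        patience=3,
        seed=0,
    )
    pool = train_pool(cfg, enc_train, enc_val, T=20, base_seed=1)
    member_train = pool.predict_members(enc_train)
    profile = vote_profile(member_train)
    _, _, y_train = stack_encoded(enc_train, gen.schema)
    flags = flag_label_noise(profile, y_train)
    truth = {d.id: d.truth for d in train_c}
    return {
        "corpus": corpus,
        "train": train_c,
        "pool": pool,
        "member_train": member_train,
        "profile": profile,
        "flags": flags,
        "truth": truth,
        "labels": y_train,
    }


@pytest.fixture
def tiny_schema():
    return TaskSchema([("site", 4), ("subsite", 8), ("behavior", 3)])


@pytest.fixture
def tiny_corpus(tiny_schema):
    """Small clean separable corpus for fast model tests."""
    gen = GeneratorConfig(
        schema=tiny_schema,
        docs_per_registry={"R1": 150, "R2": 150},
        imbalance=0.5,
        mix_rate=0.0,
        label_noise_rate=0.0,
        seed=3,
    )
    return generate_corpus(gen)
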