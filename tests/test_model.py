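"""MtCNN architecture, loss, early stopping and checkpoint tests."""

import numpy as np
import pytest

from pathdistill import (
    EarlyStopping,
    ModelConfig,
    MultitaskTextCNN,
    TaskSchema,
    build_vocab,
    encode_corpus,
    forward,
    init_model,
    load_checkpoint,
    multitask_cross_entropy,
    one_hot,
    save_checkpoint,
    stack_encoded,
    train_model,
)
from pathdistill.model import ConfigurationError


def _tiny_config(schema, vocab_size=50, **kw):
    defaults = dict(
        schema=schema,
        vocab_size=vocab_size,
        seq_len=16,
        embedding_dim=8,
        filter_widths=(2, 3),
        filters_per_width=6,
        max_epochs=5,
        patience=5,
        batch_size=16,
        seed=0,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


@pytest.fixture
def schema2():
    return TaskSchema([("site", 3), ("behavior", 4)])


class TestInit:
    def test_seed_determinism(self, schema2):
        a = init_model(_tiny_config(schema2, seed=7))
        b = init_model(_tiny_config(schema2, seed=7))
        assert a.checksum() == b.checksum()

    def test_seed_sensitivity(self, schema2):
        a = init_model(_tiny_config(schema2, seed=1))
        b = init_model(_tiny_config(schema2, seed=2))
        assert a.checksum() != b.checksum()

    def test_reference_profile_head_dimensions(self):
        cfg = ModelConfig.reference_profile(vocab_size=50, seq_len=16)
        state = init_model(cfg)
        dims = tuple(
            state.params[f"head_{name}_W"].shape[1] for name, _ in cfg.schema
        )
        assert dims == (70, 326, 7, 639, 4)
        # 3 widths x 300 filters concatenate to a 900-dim pooled vector
        assert cfg.pooled_dim == 900
        assert state.params["head_site_W"].shape[0] == 900

    def test_filter_width_exceeding_length_rejected(self, schema2):
        with pytest.raises(ConfigurationError):
            _tiny_config(schema2, seq_len=2, filter_widths=(3,))


class TestForward:
    def test_rows_sum_to_one(self, schema2):
        state = init_model(_tiny_config(schema2))
        X = np.random.default_rng(0).integers(0, 50, size=(9, 16)).astype(np.int32)
        preds = forward(state, X)
        for task in schema2.names:
            assert np.allclose(preds.probs[task].sum(axis=1), 1.0, atol=1e-5)

    def test_zeroed_head_gives_uniform(self, schema2):
        state = init_model(_tiny_config(schema2))
        state.params["head_site_W"][:] = 0.0
        state.params["head_site_b"][:] = 0.0
        X = np.random.default_rng(1).integers(0, 50, size=(4, 16)).astype(np.int32)
        preds = forward(state, X)
        assert np.allclose(preds.probs["site"], 1.0 / 3.0, atol=1e-6)

    def test_deterministic_given_weights(self, schema2):
        state = init_model(_tiny_config(schema2))
        X = np.random.default_rng(2).integers(0, 50, size=(5, 16)).astype(np.int32)
        a = forward(state, X)
        b = forward(state, X)
        for task in schema2.names:
            assert np.array_equal(a.probs[task], b.probs[task])

    def test_wrong_length_raises(self, schema2):
        state = init_model(_tiny_config(schema2))
        X = np.zeros((2, 9), dtype=np.int32)
        with pytest.raises(ValueError):
            forward(state, X)


class TestCrossEntropy:
    def test_hand_value_half_confidence(self):
        y = {"t": np.array([[0.0, 1.0, 0.0]])}
        p = {"t": np.array([[0.25, 0.5, 0.25]])}
        assert multitask_cross_entropy(y, p) == pytest.approx(0.6931, abs=1e-4)

    def test_soft_target_entropy(self):
        y = {"t": np.array([[0.5, 0.5]])}
        assert multitask_cross_entropy(y, y) == pytest.approx(np.log(2), abs=1e-6)

    def test_perfect_prediction_near_zero(self):
        y = {"t": np.array([[1.0, 0.0]])}
        assert multitask_cross_entropy(y, y) == pytest.approx(0.0, abs=1e-5)

    def test_sums_over_tasks_and_nonnegative(self):
        rng = np.random.default_rng(0)
        y = {t: one_hot(rng.integers(0, 3, 7), 3) for t in ("a", "b")}
        p = {t: rng.dirichlet(np.ones(3), size=7) for t in ("a", "b")}
        la = multitask_cross_entropy({"a": y["a"]}, {"a": p["a"]})
        lb = multitask_cross_entropy({"b": y["b"]}, {"b": p["b"]})
        total = multitask_cross_entropy(y, p)
        assert total == pytest.approx(la + lb)
        assert total >= 0

    def test_equals_nll_for_one_hot(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 4, 11)
        p = rng.dirichlet(np.ones(4), size=11)
        loss = multitask_cross_entropy({"t": one_hot(labels, 4)}, {"t": p})
        nll = -np.log(p[np.arange(11), labels]).mean()
        assert loss == pytest.approx(nll, abs=1e-6)


class TestEarlyStopping:
    def test_patience_trace_restores_best_epoch(self):
        # loss rises after epoch 2; with patience 5 training stops after
        # epoch 7 and the best epoch is 2
        losses = [1.0, 0.9, 0.95, 0.96, 0.97, 0.98, 0.99]
        stopper = EarlyStopping(patience=5)
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(epoch, loss):
                stopped_at = epoch
                break
        assert stopped_at == 7
        assert stopper.best_epoch == 2

    def test_strictly_decreasing_never_stops(self):
        stopper = EarlyStopping(patience=5)
        assert not any(
            stopper.update(e, 1.0 / e) for e in range(1, 50)
        )

    def test_plateau_counts_as_no_improvement(self):
        stopper = EarlyStopping(patience=2)
        assert not stopper.update(1, 1.0)
        assert not stopper.update(2, 1.0)
        assert stopper.update(3, 1.0)
        assert stopper.best_epoch == 1


@pytest.fixture
def encoded_tiny(tiny_corpus):
    vocab = build_vocab(tiny_corpus)
    enc = encode_corpus(tiny_corpus, vocab, 32)
    return tiny_corpus.schema, vocab, enc


class TestTraining:
    def test_empty_split_rejected(self, encoded_tiny):
        schema, vocab, enc = encoded_tiny
        cfg = _tiny_config(schema, vocab_size=len(vocab), seq_len=32)
        with pytest.raises(ValueError):
            train_model(init_model(cfg), [], enc[:10])

    def test_overfits_small_separable_corpus(self, encoded_tiny):
        """Capacity sanity: 50 separable documents are memorized to
        >=99% training accuracy."""
        schema, vocab, enc = encoded_tiny
        cfg = _tiny_config(
            schema, vocab_size=len(vocab), seq_len=32,
            embedding_dim=12, filters_per_width=12, max_epochs=60,
            patience=60, learning_rate=5e-3,
        )
        train = enc[:50]
        state = train_model(init_model(cfg), train, enc[50:60])
        preds = forward(state, train)
        _, _, y = stack_encoded(train, schema)
        for task in schema.names:
            assert (preds.argmax(task) == y[task]).mean() >= 0.99

    def test_history_records_every_epoch(self, encoded_tiny):
        schema, vocab, enc = encoded_tiny
        cfg = _tiny_config(schema, vocab_size=len(vocab), seq_len=32, max_epochs=4)
        state = train_model(init_model(cfg), enc[:60], enc[60:80])
        assert [h["epoch"] for h in state.history] == [1, 2, 3, 4]

    def test_one_hot_soft_targets_reproduce_hard_training(self, encoded_tiny):
        schema, vocab, enc = encoded_tiny
        train, val = enc[:60], enc[60:80]
        cfg = _tiny_config(schema, vocab_size=len(vocab), seq_len=32, max_epochs=3)
        hard = train_model(init_model(cfg), train, val)
        _, _, y_tr = stack_encoded(train, schema)
        _, _, y_va = stack_encoded(val, schema)
        soft_t = {n: one_hot(y_tr[n], schema.n_classes_of(n)) for n in schema.names}
        soft_v = {n: one_hot(y_va[n], schema.n_classes_of(n)) for n in schema.names}
        soft = train_model(init_model(cfg), train, val, soft_t, soft_v)
        assert [h["train_loss"] for h in soft.history] == [
            h["train_loss"] for h in hard.history
        ]
        assert [h["val_loss"] for h in soft.history] == [
            h["val_loss"] for h in hard.history
        ]

    def test_training_determinism(self, encoded_tiny):
        schema, vocab, enc = encoded_tiny
        cfg = _tiny_config(schema, vocab_size=len(vocab), seq_len=32, max_epochs=3)
        a = train_model(init_model(cfg), enc[:60], enc[60:80])
        b = train_model(init_model(cfg), enc[:60], enc[60:80])
        assert a.checksum() == b.checksum()


class TestCheckpoint:
    def test_bit_exact_round_trip(self, encoded_tiny, tmp_path):
        schema, vocab, enc = encoded_tiny
        cfg = _tiny_config(schema, vocab_size=len(vocab), seq_len=32, max_epochs=2)
        state = train_model(init_model(cfg), enc[:40], enc[40:60])
        p = tmp_path / "m.npz"
        save_checkpoint(state, p)
        back = load_checkpoint(p)
        assert back.checksum() == state.checksum()
        assert back.history == state.history
        a = forward(state, enc[:10])
        b = forward(back, enc[:10])
        for task in schema.names:
            assert np.array_equal(a.probs[task], b.probs[task])


class TestModelObjectLayer:
    def test_fit_returns_results_with_summary(self, encoded_tiny):
        schema, vocab, enc = encoded_tiny
        cfg = _tiny_config(schema, vocab_size=len(vocab), seq_len=32, max_epochs=2)
        res = MultitaskTextCNN(cfg).fit(enc[:60], enc[60:80])
        assert len(res.history) == 2
        text = res.summary()
        assert "best val loss" in text and "site" in text
        preds = res.predict(enc[:5])
        assert len(preds.ids) == 5
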