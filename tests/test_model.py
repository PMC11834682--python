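"""Sequence model: schedule closed form, architecture contracts,
gradient correctness, training loop bookkeeping, transfer continuation."""

import math

import numpy as np
import pytest

import degradict as dd
from degradict.model import ModelConfig, ReactionTransformer, TrainState, TrainingRun, learning_rate
from degradict.nn import Seq2SeqTransformer


class TestLearningRate:
    @pytest.mark.parametrize(
        "step",
        [1, 100, 4000, 100_000],
    )
    def test_matches_closed_form(self, step):
        expected = 256 ** -0.5 * min(step ** -0.5, step * 4000 ** -1.5)
        assert learning_rate(step) == pytest.approx(expected, abs=1e-12)

    def test_known_values(self):
        assert learning_rate(4000) == pytest.approx(9.8821e-4, rel=1e-4)
        assert learning_rate(1) == pytest.approx(2.4705e-7, rel=1e-4)

    def test_warmup_is_nondecreasing_then_nonincreasing(self):
        lrs = [learning_rate(s) for s in range(1, 8001)]
        assert all(b >= a for a, b in zip(lrs[:4000], lrs[1:4000]))
        assert all(b <= a for a, b in zip(lrs[3999:], lrs[4000:]))

    def test_step_zero_rejected(self):
        with pytest.raises(ValueError):
            learning_rate(0)


class TestModelConfig:
    def test_defaults_valid(self):
        cfg = ModelConfig()
        assert cfg.embedding_dim % cfg.heads == 0
        assert cfg.embedding_dim // cfg.heads == 32

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"embedding_dim": 100, "heads": 8},  # not divisible
            {"encoder_layers": 0},
            {"dropout": 1.0},
            {"dropout": -0.1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)

    def test_training_run_phases(self):
        with pytest.raises(ValueError):
            TrainingRun(phase="warmup")


@pytest.fixture
def tiny_net():
    return Seq2SeqTransformer(
        vocab_size=9, d=8, heads=2, encoder_layers=2, decoder_layers=2,
        d_ff=16, dropout=0.0, embedding_dropout=0.0, max_len=12, seed=3,
    )


class TestArchitecture:
    def test_seeded_builds_are_identical(self):
        a = Seq2SeqTransformer(vocab_size=9, d=8, heads=2, seed=5,
                               encoder_layers=1, decoder_layers=1, d_ff=16)
        b = Seq2SeqTransformer(vocab_size=9, d=8, heads=2, seed=5,
                               encoder_layers=1, decoder_layers=1, d_ff=16)
        for (na, pa), (nb, pb) in zip(a.params(), b.params()):
            assert na == nb
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_output_distributions_normalised(self, tiny_net):
        rng = np.random.default_rng(0)
        src = rng.integers(1, 9, size=(4, 6))
        tgt = rng.integers(1, 9, size=(4, 5))
        probs = tiny_net.output_distributions(src, tgt)
        assert probs.shape == (4, 5, 9)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_gradients_match_finite_differences(self, tiny_net):
        rng = np.random.default_rng(0)
        src = rng.integers(1, 9, size=(2, 5))
        tgt = rng.integers(1, 9, size=(2, 4))
        tgt_in, tgt_out = tgt[:, :-1], tgt[:, 1:]
        tiny_net.zero_grad()
        tiny_net.loss_and_grad(src, tgt_in, tgt_out)
        eps = 1e-6
        for name, p in tiny_net.params():
            flat = p.value.ravel()
            for i in rng.integers(0, flat.size, size=2):
                orig = flat[i]
                flat[i] = orig + eps
                lp = tiny_net.evaluate_loss(src, tgt_in, tgt_out)
                flat[i] = orig - eps
                lm = tiny_net.evaluate_loss(src, tgt_in, tgt_out)
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = p.grad.ravel()[i]
                assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-7), name

    def test_loss_decreases_over_first_steps(self):
        """Teacher-forced loss on a fixed batch falls within 50 Adam steps."""
        from degradict.nn import Adam

        net = Seq2SeqTransformer(
            vocab_size=8, d=16, heads=2, encoder_layers=1, decoder_layers=1,
            d_ff=32, dropout=0.0, embedding_dropout=0.0, max_len=12, seed=0,
        )
        rng = np.random.default_rng(1)
        src = rng.integers(2, 8, size=(8, 6))
        tgt = rng.integers(2, 8, size=(8, 6))
        tgt_in, tgt_out = tgt[:, :-1], tgt[:, 1:]
        opt = Adam(net.params())
        first = net.evaluate_loss(src, tgt_in, tgt_out)
        for step in range(1, 51):
            opt.zero_grad()
            net.loss_and_grad(src, tgt_in, tgt_out)
            opt.step(learning_rate(step, d=16, warmup_steps=50))
        assert net.evaluate_loss(src, tgt_in, tgt_out) < first


TOY_REACTIONS = [
    "CCCl>>CCO",
    "CCO>>CC(=O)[O-]",
    "CCBr>>CCO",
    "CCCCl>>CCCO",
    "CCCO>>CCC(=O)[O-]",
    "CCCBr>>CCCO",
    "CCCN>>CCCO",
    "CCCCN>>CCCCO",
    "CCCCO>>CCCC(=O)[O-]",
    "CC(=O)[O-]>>O=C=O",
]


def _tiny_estimator(**overrides):
    params = dict(
        encoder_layers=1, decoder_layers=1, heads=2, embedding_dim=16,
        feedforward_dim=32, batch_size=4, finetune_batch_size=2,
        max_epochs=2, patience=10, warmup_steps=400,
        standardize_inputs=False, random_state=0,
    )
    params.update(overrides)
    return ReactionTransformer(**params)


class TestTrainingLoop:
    def test_step_counter_advances_by_batches_per_epoch(self):
        est = _tiny_estimator(max_epochs=1, validation_fraction=0.2)
        est.fit(TOY_REACTIONS)
        n_train = len(TOY_REACTIONS) - 2  # 20% of 10 held out
        assert est.state_.step_num == math.ceil(n_train / est.batch_size)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            _tiny_estimator().fit([])

    def test_early_stopping_patience(self, monkeypatch):
        """Validation losses 1.0, 0.9 then ten non-improving epochs stop
        training at epoch 12, well before max_epochs."""
        est = _tiny_estimator(max_epochs=250, patience=10)
        scripted = iter([1.0, 0.9] + [0.91] * 50)
        monkeypatch.setattr(
            ReactionTransformer, "_evaluate", lambda self, enc, bs: next(scripted)
        )
        est.fit(TOY_REACTIONS)
        assert est.state_.epoch == 12
        assert est.state_.epochs_since_improvement == 10
        assert est.state_.best_validation_loss == 0.9

    def test_never_trains_past_max_epochs(self, monkeypatch):
        est = _tiny_estimator(max_epochs=5, patience=10)
        monkeypatch.setattr(
            ReactionTransformer, "_evaluate", lambda self, enc, bs: 1.0
        )
        est.fit(TOY_REACTIONS)
        assert est.state_.epoch == 5

    def test_equal_seeds_give_equal_models(self):
        a = _tiny_estimator().fit(TOY_REACTIONS)
        b = _tiny_estimator().fit(TOY_REACTIONS)
        for (na, pa), (nb, pb) in zip(a.model_.params(), b.model_.params()):
            np.testing.assert_array_equal(pa.value, pb.value)


class TestFinetune:
    def test_requires_fitted_model(self):
        with pytest.raises(RuntimeError):
            _tiny_estimator().finetune(TOY_REACTIONS)

    def test_step_counter_continues(self):
        est = _tiny_estimator(max_epochs=2).fit(TOY_REACTIONS)
        steps_after_pretrain = est.state_.step_num
        assert steps_after_pretrain > 0
        est.finetune(TOY_REACTIONS, max_epochs=1)
        # batch size 2, 9 training reactions after the validation split
        assert est.state_.step_num == steps_after_pretrain + 5
        # the first fine-tune record's lr sits on the schedule continuation
        finetune_epochs = [h for h in est.history_ if h["phase"] == "finetune"]
        assert finetune_epochs[0]["lr"] == pytest.approx(
            learning_rate(est.state_.step_num, d=16, warmup_steps=400)
        )

    def test_zero_epoch_finetune_is_identity(self):
        est = _tiny_estimator(max_epochs=2).fit(TOY_REACTIONS)
        before = {n: p.value.copy() for n, p in est.model_.params()}
        est.finetune(TOY_REACTIONS, max_epochs=0)
        for n, p in est.model_.params():
            np.testing.assert_array_equal(p.value, before[n])

    def test_finetune_batch_must_be_smaller(self):
        with pytest.raises(ValueError):
            _tiny_estimator(batch_size=4, finetune_batch_size=4).fit(TOY_REACTIONS)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        est = _tiny_estimator(max_epochs=2).fit(TOY_REACTIONS)
        path = tmp_path / "model.npz"
        est.save(path)
        loaded = ReactionTransformer.load(path)
        assert loaded.state_.step_num == est.state_.step_num
        assert loaded.vocab_.token_to_index == est.vocab_.token_to_index
        for (na, pa), (nb, pb) in zip(est.model_.params(), loaded.model_.params()):
            np.testing.assert_array_equal(pa.value, pb.value)
        a = est.predict(["CCCl"], beam_width=2)
        b = loaded.predict(["CCCl"], beam_width=2)
        assert a == b

    def test_sklearn_get_set_params(self):
        est = _tiny_estimator()
        params = est.get_params()
        assert params["embedding_dim"] == 16
        est.set_params(embedding_dim=32)
        assert est.embedding_dim == 32
        with pytest.raises(ValueError):
            est.set_params(nonsense=1)
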