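"""The sequence model: configuration, training schedule, estimator.

:class:`ReactionTransformer` is a scikit-learn style estimator around the
NumPy encoder-decoder transformer.  ``fit`` performs teacher-forced
training with the inverse-square-root warmup schedule and early stopping
on validation loss; ``finetune`` continues training on a second corpus
with a smaller batch size and — deliberately — *without* resetting the
global optimiser-step counter, so the learning-rate schedule resumes
where pre-training left off.  ``predict`` beam-decodes ranked candidate
product sets.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .chem import Reaction, standardize
from .nn import Adam, Seq2SeqTransformer
from .tokenizer import Vocabulary, build_vocab, tokenize

__all__ = [
    "ModelConfig",
    "TrainState",
    "TrainingRun",
    "learning_rate",
    "build_model",
    "ReactionTransformer",
]


@dataclass
class ModelConfig:
    """Transformer hyperparameters.

    Defaults are the full-scale settings (4+4 layers, 8 heads, d=256,
    feed-forward 2048, dropout 0.1, maximum sequence length 276 tokens
    including the start/end symbols, 4000 warmup steps).
    """

    encoder_layers: int = 4
    decoder_layers: int = 4
    heads: int = 8
    embedding_dim: int = 256
    feedforward_dim: int = 2048
    dropout: float = 0.1
    embedding_dropout: float = 0.1
    max_seq_len: int = 276
    warmup_steps: int = 4000

    def __post_init__(self):
        counts = (
            self.encoder_layers,
            self.decoder_layers,
            self.heads,
            self.embedding_dim,
            self.feedforward_dim,
            self.max_seq_len,
            self.warmup_steps,
        )
        if any(int(c) != c or c <= 0 for c in counts):
            raise ValueError("all ModelConfig counts must be positive integers")
        if self.embedding_dim % self.heads:
            raise ValueError("embedding_dim must be divisible by heads")
        for frac in (self.dropout, self.embedding_dropout):
            if not 0.0 <= frac < 1.0:
                raise ValueError("dropout fractions must lie in [0, 1)")


@dataclass
class TrainState:
    """Bookkeeping that survives across training phases.

    ``step_num`` counts optimiser updates globally and is never reset by
    fine-tuning, which is what makes the learning-rate schedule continue
    rather than re-warm.
    """

    step_num: int = 0
    epoch: int = 0
    best_validation_loss: float = math.inf
    epochs_since_improvement: int = 0
    rng_seed: int = 0


@dataclass
class TrainingRun:
    """One training phase: pre-training or fine-tuning."""

    phase: str = "pretrain"
    batch_size: int = 128
    max_epochs: int = 250
    early_stop_patience: int = 10

    def __post_init__(self):
        if self.phase not in ("pretrain", "finetune"):
            raise ValueError("phase must be 'pretrain' or 'finetune'")
        if self.batch_size < 1 or self.max_epochs < 0 or self.early_stop_patience < 1:
            raise ValueError("invalid TrainingRun counts")


def learning_rate(
    step_num: int, d: int = 256, warmup_steps: int = 4000
) -> float:
    """Inverse-square-root schedule with linear warmup.

    ``lr = d^-0.5 * min(step^-0.5, step * warmup^-1.5)``: linear growth
    over the first ``warmup_steps`` optimiser steps, then decay with the
    inverse square root of the step counter.  Both branches meet at
    ``step_num == warmup_steps``.
    """
    step_num = int(step_num)
    if step_num <= 0:
        raise ValueError("step_num must be >= 1")
    return d ** -0.5 * min(step_num ** -0.5, step_num * warmup_steps ** -1.5)


def build_model(
    config: ModelConfig, vocab: Vocabulary, seed: int = 0
) -> Seq2SeqTransformer:
    """Instantiate the transformer for a vocabulary (seeded, deterministic)."""
    return Seq2SeqTransformer(
        vocab_size=len(vocab),
        d=config.embedding_dim,
        heads=config.heads,
        encoder_layers=config.encoder_layers,
        decoder_layers=config.decoder_layers,
        d_ff=config.feedforward_dim,
        dropout=config.dropout,
        embedding_dropout=config.embedding_dropout,
        max_len=config.max_seq_len,
        pad_id=vocab.pad,
        seed=seed,
    )


ReactionLike = Union[str, Reaction, Tuple[str, str]]


def _as_pair(r: ReactionLike) -> Tuple[str, str]:
    if isinstance(r, Reaction):
        return r.reactant_smiles, r.product_smiles
    if isinstance(r, str):
        rx = Reaction.from_smiles(r)
        return rx.reactant_smiles, rx.product_smiles
    a, b = r
    return a, b


class ReactionTransformer:
    """Seq2seq product prediction as a scikit-learn style estimator.

    ``fit`` trains on reactions (``"reactant>>products"`` strings,
    ``(reactant, products)`` pairs or :class:`~degradict.chem.Reaction`);
    ``finetune`` transfers the trained weights to a new corpus;
    ``predict`` returns ranked ``(product_smiles, probability)``
    candidates per input reactant (see :mod:`degradict.decoding`).

    Parameters
    ----------
    encoder_layers, decoder_layers, heads, embedding_dim, feedforward_dim,
    dropout, embedding_dropout, max_seq_len, warmup_steps
        Architecture and schedule, see :class:`ModelConfig`.
    batch_size, finetune_batch_size
        Pre-training and fine-tuning batch sizes (fine-tuning uses the
        smaller batch to get more updates per epoch on small corpora).
    max_epochs, patience
        Epoch cap and early-stopping patience; training stops when the
        validation loss has not strictly decreased for ``patience``
        consecutive epochs.
    validation_fraction
        Share of the training reactions held out for early stopping when
        no explicit validation set is passed.
    standardize_inputs
        Standardise reaction SMILES before tokenising (disable when the
        corpus is already standardised).
    random_state
        Seed for initialisation, shuffling and dropout.

    Attributes
    ----------
    model_ : Seq2SeqTransformer
    vocab_ : Vocabulary
    state_ : TrainState
    config_ : ModelConfig
    history_ : list of per-epoch dicts (phase, epoch, train/valid loss, lr)
    """

    def __init__(
        self,
        encoder_layers: int = 4,
        decoder_layers: int = 4,
        heads: int = 8,
        embedding_dim: int = 256,
        feedforward_dim: int = 2048,
        dropout: float = 0.1,
        embedding_dropout: float = 0.1,
        max_seq_len: int = 276,
        warmup_steps: int = 4000,
        batch_size: int = 128,
        finetune_batch_size: int = 64,
        max_epochs: int = 250,
        patience: int = 10,
        validation_fraction: float = 0.1,
        standardize_inputs: bool = True,
        random_state: int = 0,
    ):
        self.encoder_layers = encoder_layers
        self.decoder_layers = decoder_layers
        self.heads = heads
        self.embedding_dim = embedding_dim
        self.feedforward_dim = feedforward_dim
        self.dropout = dropout
        self.embedding_dropout = embedding_dropout
        self.max_seq_len = max_seq_len
        self.warmup_steps = warmup_steps
        self.batch_size = batch_size
        self.finetune_batch_size = finetune_batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.standardize_inputs = standardize_inputs
        self.random_state = random_state

    # ------------------------------------------------------------ sklearn API
    _PARAM_NAMES = (
        "encoder_layers", "decoder_layers", "heads", "embedding_dim",
        "feedforward_dim", "dropout", "embedding_dropout", "max_seq_len",
        "warmup_steps", "batch_size", "finetune_batch_size", "max_epochs",
        "patience", "validation_fraction", "standardize_inputs", "random_state",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._PARAM_NAMES}

    def set_params(self, **params) -> "ReactionTransformer":
        for k, v in params.items():
            if k not in self._PARAM_NAMES:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> ModelConfig:
        return ModelConfig(
            encoder_layers=self.encoder_layers,
            decoder_layers=self.decoder_layers,
            heads=self.heads,
            embedding_dim=self.embedding_dim,
            feedforward_dim=self.feedforward_dim,
            dropout=self.dropout,
            embedding_dropout=self.embedding_dropout,
            max_seq_len=self.max_seq_len,
            warmup_steps=self.warmup_steps,
        )

    # ------------------------------------------------------------ data prep
    def _prepare(self, reactions: Sequence[ReactionLike]) -> List[Tuple[str, str]]:
        pairs = []
        for r in reactions:
            src, tgt = _as_pair(r)
            if self.standardize_inputs:
                src, tgt = standardize(src), standardize(tgt)
            pairs.append((src, tgt))
        return pairs

    def _encode_pairs(
        self, pairs: Sequence[Tuple[str, str]], warn_skipped: bool = True
    ) -> List[Tuple[List[int], List[int]]]:
        out = []
        skipped = 0
        for src, tgt in pairs:
            s = self.vocab_.encode(tokenize(src), add_specials=True)
            t = self.vocab_.encode(tokenize(tgt), add_specials=True)
            if len(s) > self.max_seq_len or len(t) > self.max_seq_len:
                skipped += 1  # over-length sequences are rejected, not truncated
                continue
            out.append((s, t))
        if skipped and warn_skipped:
            import warnings

            warnings.warn(
                f"skipped {skipped} reaction(s) longer than max_seq_len="
                f"{self.max_seq_len}",
                stacklevel=3,
            )
        return out

    @staticmethod
    def _pad_batch(
        encoded: Sequence[Tuple[List[int], List[int]]]
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        smax = max(len(s) for s, _ in encoded)
        tmax = max(len(t) for _, t in encoded)
        B = len(encoded)
        src = np.zeros((B, smax), dtype=np.int64)
        tgt = np.zeros((B, tmax), dtype=np.int64)
        for i, (s, t) in enumerate(encoded):
            src[i, : len(s)] = s
            tgt[i, : len(t)] = t
        return src, tgt[:, :-1], tgt[:, 1:]

    # ------------------------------------------------------------- training
    def fit(
        self,
        X: Sequence[ReactionLike],
        y=None,
        validation_data: Optional[Sequence[ReactionLike]] = None,
    ) -> "ReactionTransformer":
        """Train from scratch (the pre-training phase)."""
        if len(X) == 0:
            raise ValueError("cannot fit on an empty reaction list")
        if self.finetune_batch_size >= self.batch_size:
            raise ValueError(
                "finetune_batch_size must be smaller than batch_size"
            )
        self.config_ = self._config()
        pairs = self._prepare(X)
        corpus = [tokenize(s) for pair in pairs for s in pair]
        self.vocab_ = build_vocab(corpus)
        self.model_ = build_model(self.config_, self.vocab_, seed=self.random_state)
        self.optimizer_ = Adam(self.model_.params())
        self.state_ = TrainState(rng_seed=self.random_state)
        self.history_: List[dict] = []
        self._shuffle_rng = np.random.default_rng(self.random_state + 1)
        run = TrainingRun(
            phase="pretrain",
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            early_stop_patience=self.patience,
        )
        self._run_phase(pairs, validation_data, run)
        return self

    def finetune(
        self,
        X: Sequence[ReactionLike],
        validation_data: Optional[Sequence[ReactionLike]] = None,
        max_epochs: Optional[int] = None,
    ) -> "ReactionTransformer":
        """Transfer the fitted model to a new corpus.

        All weights stay trainable and the optimiser-step counter (hence
        the learning-rate schedule) continues from the end of
        pre-training.  Uses the smaller ``finetune_batch_size``.
        """
        if not hasattr(self, "model_"):
            raise RuntimeError("finetune requires a fitted (pre-trained) model")
        run = TrainingRun(
            phase="finetune",
            batch_size=self.finetune_batch_size,
            max_epochs=self.max_epochs if max_epochs is None else max_epochs,
            early_stop_patience=self.patience,
        )
        pairs = self._prepare(X)
        # early-stopping bookkeeping restarts for the new phase; the step
        # counter does not.
        self.state_.best_validation_loss = math.inf
        self.state_.epochs_since_improvement = 0
        self._run_phase(pairs, validation_data, run)
        return self

    def _run_phase(
        self,
        pairs: List[Tuple[str, str]],
        validation_data: Optional[Sequence[ReactionLike]],
        run: TrainingRun,
    ) -> None:
        if validation_data is not None:
            valid_pairs = self._prepare(validation_data)
        else:
            n_valid = max(1, int(round(len(pairs) * self.validation_fraction)))
            if n_valid >= len(pairs):
                raise ValueError("not enough reactions to split off validation data")
            order = self._shuffle_rng.permutation(len(pairs))
            valid_pairs = [pairs[i] for i in order[:n_valid]]
            pairs = [pairs[i] for i in order[n_valid:]]
        train_enc = self._encode_pairs(pairs)
        valid_enc = self._encode_pairs(valid_pairs)
        if not train_enc:
            raise ValueError("no trainable reactions (all invalid or over-length)")
        state = self.state_
        for _ in range(run.max_epochs):
            order = self._shuffle_rng.permutation(len(train_enc))
            losses = []
            for start in range(0, len(order), run.batch_size):
                batch = [train_enc[i] for i in order[start : start + run.batch_size]]
                src, tgt_in, tgt_out = self._pad_batch(batch)
                self.optimizer_.zero_grad()
                loss = self.model_.loss_and_grad(src, tgt_in, tgt_out)
                state.step_num += 1
                lr = learning_rate(
                    state.step_num,
                    d=self.config_.embedding_dim,
                    warmup_steps=self.config_.warmup_steps,
                )
                self.optimizer_.step(lr)
                losses.append(loss)
            state.epoch += 1
            valid_loss = self._evaluate(valid_enc, run.batch_size)
            record = {
                "phase": run.phase,
                "epoch": state.epoch,
                "step_num": state.step_num,
                "train_loss": float(np.mean(losses)),
                "valid_loss": valid_loss,
                "lr": learning_rate(
                    max(state.step_num, 1),
                    d=self.config_.embedding_dim,
                    warmup_steps=self.config_.warmup_steps,
                ),
            }
            self.history_.append(record)
            if valid_loss < state.best_validation_loss:
                state.best_validation_loss = valid_loss
                state.epochs_since_improvement = 0
            else:
                state.epochs_since_improvement += 1
                if state.epochs_since_improvement >= run.early_stop_patience:
                    break

    def _evaluate(
        self, encoded: Sequence[Tuple[List[int], List[int]]], batch_size: int
    ) -> float:
        if not encoded:
            return math.nan
        losses, weights = [], []
        for start in range(0, len(encoded), batch_size):
            batch = encoded[start : start + batch_size]
            src, tgt_in, tgt_out = self._pad_batch(batch)
            losses.append(self.model_.evaluate_loss(src, tgt_in, tgt_out))
            weights.append(int((tgt_out != 0).sum()))
        return float(np.average(losses, weights=weights))

    # ------------------------------------------------------------ inference
    def predict(
        self,
        X: Sequence[str],
        beam_width: int = 8,
        max_len: Optional[int] = None,
    ) -> List[List[Tuple[str, float]]]:
        """Ranked candidate product SMILES with probabilities per reactant.

        Every candidate is the detokenised decoder output; validity /
        standardisation of the candidates is the caller's concern (see
        :func:`degradict.decoding.candidates_to_product_sets`).
        """
        from .decoding import DecodeConfig, beam_decode

        self._check_fitted()
        config = DecodeConfig(
            beam_width=beam_width,
            max_len=self.max_seq_len if max_len is None else max_len,
        )
        out = []
        for smi in X:
            src = standardize(smi) if self.standardize_inputs else smi
            cands = beam_decode(self, src, config)
            out.append([(c.smiles, c.probability) for c in cands])
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("this ReactionTransformer is not fitted yet")

    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Checkpoint: parameters + TrainState + config + vocabulary."""
        self._check_fitted()
        meta = {
            "params": self.get_params(),
            "config": asdict(self.config_),
            "state": asdict(self.state_),
            "history": self.history_,
            "vocab": sorted(
                self.vocab_.token_to_index.items(), key=lambda kv: kv[1]
            ),
            "vocab_hash": self.vocab_.content_hash(),
        }
        arrays = {f"w::{k}": v for k, v in self.model_.state_dict().items()}
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "ReactionTransformer":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        est = cls(**meta["params"])
        est.config_ = ModelConfig(**meta["config"])
        est.state_ = TrainState(**meta["state"])
        est.history_ = meta["history"]
        est.vocab_ = Vocabulary(dict((t, int(i)) for t, i in meta["vocab"]))
        if est.vocab_.content_hash() != meta["vocab_hash"]:
            raise ValueError("vocabulary hash mismatch in checkpoint")
        est.model_ = build_model(est.config_, est.vocab_, seed=est.state_.rng_seed)
        est.model_.load_state_dict(
            {k[3:]: data[k] for k in data.files if k.startswith("w::")}
        )
        est.optimizer_ = Adam(est.model_.params())
        est._shuffle_rng = np.random.default_rng(est.state_.rng_seed + 1)
        return est
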