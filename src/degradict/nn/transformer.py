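"""Encoder-decoder transformer assembled from the NumPy layers.

Post-norm residual blocks, sinusoidal positions, padding masked out of
both attention and the loss, causal masking in the decoder.  The class
exposes three entry points:

* :meth:`loss_and_grad` - teacher-forced cross-entropy plus backprop
  (used by the training loop),
* :meth:`output_distributions` - per-position softmax over the
  vocabulary (used by tests and diagnostics),
* :meth:`encode` / :meth:`next_token_logprobs` - split forward pass for
  autoregressive beam decoding, where the encoder memory is computed
  once per reactant and reused across beams and steps.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .layers import (
    NEG_INF,
    Dropout,
    Embedding,
    FeedForward,
    LayerNorm,
    Linear,
    Module,
    MultiHeadAttention,
    cross_entropy,
    log_softmax,
    softmax,
)


class EncoderLayer(Module):
    def __init__(self, rng, d, heads, d_ff, dropout):
        self.attn = MultiHeadAttention(rng, d, heads, dropout)
        self.norm1 = LayerNorm(d)
        self.ffn = FeedForward(rng, d, d_ff, dropout)
        self.norm2 = LayerNorm(d)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, x, src_mask, train):
        a = self.drop1.forward(self.attn.forward(x, x, src_mask, train), train)
        x = self.norm1.forward(x + a)
        f = self.drop2.forward(self.ffn.forward(x, train), train)
        return self.norm2.forward(x + f)

    def backward(self, g):
        g = self.norm2.backward(g)
        gf = self.ffn.backward(self.drop2.backward(g))
        g = g + gf
        g = self.norm1.backward(g)
        ga = self.drop1.backward(g)
        dq, dkv = self.attn.backward(ga)
        return g + dq + dkv


class DecoderLayer(Module):
    def __init__(self, rng, d, heads, d_ff, dropout):
        self.self_attn = MultiHeadAttention(rng, d, heads, dropout)
        self.norm1 = LayerNorm(d)
        self.cross_attn = MultiHeadAttention(rng, d, heads, dropout)
        self.norm2 = LayerNorm(d)
        self.ffn = FeedForward(rng, d, d_ff, dropout)
        self.norm3 = LayerNorm(d)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)
        self.drop3 = Dropout(dropout, rng)

    def forward(self, x, memory, tgt_mask, mem_mask, train):
        a = self.drop1.forward(self.self_attn.forward(x, x, tgt_mask, train), train)
        x = self.norm1.forward(x + a)
        c = self.drop2.forward(
            self.cross_attn.forward(x, memory, mem_mask, train), train
        )
        x = self.norm2.forward(x + c)
        f = self.drop3.forward(self.ffn.forward(x, train), train)
        return self.norm3.forward(x + f)

    def backward(self, g) -> Tuple[np.ndarray, np.ndarray]:
        g = self.norm3.backward(g)
        gf = self.ffn.backward(self.drop3.backward(g))
        g = g + gf
        g = self.norm2.backward(g)
        gc = self.drop2.backward(g)
        dq_c, dmem = self.cross_attn.backward(gc)
        g = g + dq_c
        g = self.norm1.backward(g)
        ga = self.drop1.backward(g)
        dq, dkv = self.self_attn.backward(ga)
        return g + dq + dkv, dmem


class Seq2SeqTransformer(Module):
    """Sequence-to-sequence transformer over a shared SMILES vocabulary.

    Parameters mirror the standard architecture: ``d`` embedding width,
    ``heads`` attention heads, separate encoder/decoder stacks, ``d_ff``
    feed-forward width, residual ``dropout`` and ``embedding_dropout``.
    Initialisation is fully determined by ``seed``.
    """

    def __init__(
        self,
        vocab_size: int,
        d: int = 256,
        heads: int = 8,
        encoder_layers: int = 4,
        decoder_layers: int = 4,
        d_ff: int = 2048,
        dropout: float = 0.1,
        embedding_dropout: float = 0.1,
        max_len: int = 276,
        pad_id: int = 0,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.vocab_size = vocab_size
        self.d = d
        self.max_len = max_len
        self.pad_id = pad_id
        self.src_embed = Embedding(rng, vocab_size, d, max_len, embedding_dropout)
        self.tgt_embed = Embedding(rng, vocab_size, d, max_len, embedding_dropout)
        self.encoder = [
            EncoderLayer(rng, d, heads, d_ff, dropout) for _ in range(encoder_layers)
        ]
        self.decoder = [
            DecoderLayer(rng, d, heads, d_ff, dropout) for _ in range(decoder_layers)
        ]
        self.out_proj = Linear(rng, d, vocab_size)
        self._rng = rng

    # ------------------------------------------------------------------ masks
    def _pad_mask(self, ids: np.ndarray) -> np.ndarray:
        """(B, 1, 1, T) additive mask hiding padding keys."""
        return np.where(ids[:, None, None, :] == self.pad_id, NEG_INF, 0.0)

    @staticmethod
    def _causal_mask(T: int) -> np.ndarray:
        return np.where(np.triu(np.ones((T, T)), k=1) > 0, NEG_INF, 0.0)[None, None]

    # ---------------------------------------------------------------- forward
    def forward(
        self, src_ids: np.ndarray, tgt_in_ids: np.ndarray, train: bool = False
    ) -> np.ndarray:
        """Teacher-forced forward pass returning logits (B, T_tgt, V)."""
        src_mask = self._pad_mask(src_ids)
        tgt_mask = self._causal_mask(tgt_in_ids.shape[1]) + self._pad_mask(tgt_in_ids)
        x = self.src_embed.forward(src_ids, train)
        for layer in self.encoder:
            x = layer.forward(x, src_mask, train)
        memory = x
        y = self.tgt_embed.forward(tgt_in_ids, train)
        for layer in self.decoder:
            y = layer.forward(y, memory, tgt_mask, src_mask, train)
        return self.out_proj.forward(y)

    def output_distributions(
        self, src_ids: np.ndarray, tgt_in_ids: np.ndarray
    ) -> np.ndarray:
        """Probability distribution over the vocabulary per target position."""
        return softmax(self.forward(src_ids, tgt_in_ids, train=False))

    def loss_and_grad(
        self, src_ids: np.ndarray, tgt_in_ids: np.ndarray, tgt_out_ids: np.ndarray
    ) -> float:
        """Cross-entropy on product tokens + full backward pass.

        Gradients are *accumulated* into the parameters; call
        ``zero_grad`` (or ``Adam.zero_grad``) between steps.
        """
        logits = self.forward(src_ids, tgt_in_ids, train=True)
        loss_mask = (tgt_out_ids != self.pad_id).astype(np.float64)
        loss, dlogits = cross_entropy(logits, tgt_out_ids, loss_mask)
        g = self.out_proj.backward(dlogits)
        dmem_total = 0.0
        for layer in reversed(self.decoder):
            g, dmem = layer.backward(g)
            dmem_total = dmem_total + dmem
        self.tgt_embed.backward(g)
        g = dmem_total
        for layer in reversed(self.encoder):
            g = layer.backward(g)
        self.src_embed.backward(g)
        return loss

    def evaluate_loss(
        self, src_ids: np.ndarray, tgt_in_ids: np.ndarray, tgt_out_ids: np.ndarray
    ) -> float:
        """Cross-entropy without dropout or gradients (validation)."""
        logits = self.forward(src_ids, tgt_in_ids, train=False)
        loss_mask = (tgt_out_ids != self.pad_id).astype(np.float64)
        loss, _ = cross_entropy(logits, tgt_out_ids, loss_mask)
        return loss

    # --------------------------------------------------------------- decoding
    def encode(self, src_ids: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Run the encoder once; returns (memory, src_pad_mask)."""
        src_mask = self._pad_mask(src_ids)
        x = self.src_embed.forward(src_ids, train=False)
        for layer in self.encoder:
            x = layer.forward(x, src_mask, train=False)
        return x, src_mask

    def next_token_logprobs(
        self, memory: np.ndarray, src_mask: np.ndarray, tgt_in_ids: np.ndarray
    ) -> np.ndarray:
        """Log-probabilities of the next token for each row of ``tgt_in_ids``.

        ``memory``/``src_mask`` may have batch 1 and are broadcast across
        the decoding beams.
        """
        B = tgt_in_ids.shape[0]
        if memory.shape[0] == 1 and B > 1:
            memory = np.broadcast_to(memory, (B,) + memory.shape[1:])
            src_mask = np.broadcast_to(src_mask, (B,) + src_mask.shape[1:])
        tgt_mask = self._causal_mask(tgt_in_ids.shape[1])
        y = self.tgt_embed.forward(tgt_in_ids, train=False)
        for layer in self.decoder:
            y = layer.forward(y, memory, tgt_mask, src_mask, train=False)
        logits = self.out_proj.forward(y[:, -1:, :])[:, 0, :]
        return log_softmax(logits)

    # ------------------------------------------------------------- state I/O
    def state_dict(self) -> dict:
        return {name: p.value.copy() for name, p in self.params()}

    def load_state_dict(self, state: dict) -> None:
        mine = dict(self.params())
        if set(mine) != set(state):
            raise ValueError("parameter names do not match this architecture")
        for name, value in state.items():
            if mine[name].value.shape != value.shape:
                raise ValueError(f"shape mismatch for {name}")
            mine[name].value[...] = value
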