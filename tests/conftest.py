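"""Shared fixtures: synthetic corpora, a trained tiny model, and a
table-driven fake sequence model for exercising beam search and pathway
expansion against hand-computable probabilities."""

from __future__ import annotations

import math
from typing import Dict, List, Sequence

import numpy as np
import pytest

import degradict as dd
from degradict.tokenizer import build_vocab, tokenize

# ---------------------------------------------------------------------------
# Desk-scale study conditions, used by the training-based tests and mirrored
# by scripts/acceptance.py: a 2-layer/64-dim transformer, batch sizes 128/64,
# warmup scaled to 400 steps, 2000 training reactions from the rule grammar.
# ---------------------------------------------------------------------------
TINY_MODEL_PARAMS = dict(
    encoder_layers=2,
    decoder_layers=2,
    heads=4,
    embedding_dim=64,
    feedforward_dim=256,
    batch_size=128,
    finetune_batch_size=64,
    max_epochs=60,
    patience=10,
    warmup_steps=400,
    standardize_inputs=False,
)
N_TRAIN_REACTIONS = 2000
N_TEST_REACTIONS = 200


@pytest.fixture(scope="session")
def grammar():
    return dd.default_grammar()


@pytest.fixture(scope="session")
def train_corpus(grammar):
    return dd.generate_pathways(grammar, n=1500, max_depth=4, seed=11)


@pytest.fixture(scope="session")
def test_corpus(grammar):
    return dd.generate_pathways(grammar, n=160, max_depth=4, seed=99)


@pytest.fixture(scope="session")
def train_reactions(train_corpus):
    return [r.to_smiles() for r in train_corpus.reactions][:N_TRAIN_REACTIONS]


@pytest.fixture(scope="session")
def test_reactions(test_corpus):
    return test_corpus.reactions[:N_TEST_REACTIONS]


@pytest.fixture(scope="session")
def trained_estimator(train_reactions):
    """The tiny reference model, trained once per session (~2-3 min)."""
    est = dd.ReactionTransformer(random_state=0, **TINY_MODEL_PARAMS)
    est.fit(train_reactions)
    return est


def records_from_reactions(estimator, reactions, beam_width=5):
    """Group reactions by reactant, decode each reactant once, and build
    evaluation records."""
    from collections import defaultdict

    by_reactant = defaultdict(list)
    for r in reactions:
        by_reactant[r.reactant_smiles].append(frozenset(r.products))
    records = []
    for reactant, true_sets in by_reactant.items():
        cands = dd.beam_decode(
            estimator, reactant, dd.DecodeConfig(beam_width=beam_width)
        )
        preds = dd.candidates_to_product_sets(cands)
        records.append(
            dd.PredictionRecord(
                reactant=reactant,
                true_sets=true_sets,
                candidates=[
                    dd.Candidate(p.products, p.probability) for p in preds
                ],
            )
        )
    return records


# ---------------------------------------------------------------------------
# Table-driven fake model: per source compound, an explicit distribution over
# complete output strings.  Next-token log-probabilities are derived from the
# prefix tree, so a sequence's decoded probability equals its table weight
# exactly -- making beam search comparable against exhaustive enumeration.
# ---------------------------------------------------------------------------


class _StringTableNetwork:
    def __init__(self, vocab, tables: Dict[str, Dict[str, float]]):
        self.vocab = vocab
        # src smiles -> list of (token-id tuple, weight)
        self.tables = {
            src: [
                (tuple(vocab.encode(tokenize(s))), w) for s, w in table.items()
            ]
            for src, table in tables.items()
        }
        self._current_src = None

    def encode(self, src_ids):
        body = [int(i) for i in src_ids[0] if i not in (0, 1, 2)]
        self._current_src = dd.detokenize(self.vocab.decode(body))
        memory = np.zeros((1, src_ids.shape[1], 1))
        src_mask = np.zeros((1, 1, 1, src_ids.shape[1]))
        return memory, src_mask

    def next_token_logprobs(self, memory, src_mask, tgt_in_ids):
        # unknown source compounds are terminal: they emit EOS immediately
        table = self.tables.get(self._current_src, [])
        V = len(self.vocab)
        out = np.full((tgt_in_ids.shape[0], V), -np.inf)
        for row, ids in enumerate(tgt_in_ids):
            prefix = tuple(int(i) for i in ids[1:])  # strip SOS
            probs = np.zeros(V)
            for seq, w in table:
                if seq[: len(prefix)] != prefix:
                    continue
                if len(seq) == len(prefix):
                    probs[self.vocab.eos] += w
                else:
                    probs[seq[len(prefix)]] += w
            if not prefix:
                # any table mass missing from a distribution goes to an
                # immediate EOS (an empty candidate, invalid downstream), so
                # decoded sequence probabilities equal raw table weights
                probs[self.vocab.eos] += max(0.0, 1.0 - probs.sum())
            total = probs.sum()
            if total > 0:
                with np.errstate(divide="ignore"):
                    out[row] = np.where(probs > 0, np.log(probs / total), -np.inf)
        return out


class FakeEstimator:
    """Quacks like a fitted ReactionTransformer for decoding/pathway code."""

    def __init__(self, tables: Dict[str, Dict[str, float]]):
        corpus = [tokenize(s) for s in tables] + [
            tokenize(s) for t in tables.values() for s in t
        ]
        self.vocab_ = build_vocab(corpus)
        self.model_ = _StringTableNetwork(self.vocab_, tables)
        self.standardize_inputs = False


@pytest.fixture
def fake_estimator_factory():
    return FakeEstimator
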