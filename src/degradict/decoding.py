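"""Beam-search decoding of ranked candidate product sequences.

The decoder expands all live beams one token at a time from the
sequence-start symbol; at every step the ``beam_width`` most probable
sequences survive, finished sequences (those that emitted the end
symbol) competing for slots alongside unfinished ones.  A sequence's
probability is the product of the model's per-token probabilities —
no length normalisation — because downstream thresholding and pathway
conditional probabilities need true products.  Scores are accumulated
in log space and exponentiated at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .chem import InvalidSmilesError, RuleApplicationError, standardize
from .tokenizer import detokenize

__all__ = [
    "DecodeConfig",
    "BeamCandidate",
    "ProductPrediction",
    "beam_decode",
    "candidates_to_product_sets",
]


@dataclass(frozen=True)
class DecodeConfig:
    """Beam width 8 is used for single-reaction ranking, 5 for recursive
    pathway prediction (wider beams get expensive when every predicted
    product is itself re-decoded)."""

    beam_width: int = 8
    max_len: int = 276

    def __post_init__(self):
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.max_len < 2:
            raise ValueError("max_len must allow at least one token plus EOS")


@dataclass(frozen=True)
class BeamCandidate:
    """One decoded sequence: its SMILES tokens and raw probability."""

    tokens: Tuple[str, ...]
    probability: float
    log_probability: float
    finished: bool = True

    @property
    def smiles(self) -> str:
        return detokenize(self.tokens)


def beam_decode(estimator, reactant_smiles: str, config: DecodeConfig) -> List[BeamCandidate]:
    """Beam-search the product sequences for one reactant.

    ``estimator`` is a fitted :class:`~degradict.model.ReactionTransformer`.
    Returns exactly ``beam_width`` candidates sorted by probability
    descending (fewer only when the search space is exhausted).  Ties are
    broken lexicographically on token indices for determinism.
    """
    from .tokenizer import tokenize

    vocab = estimator.vocab_
    model = estimator.model_
    src = np.asarray(
        [vocab.encode(tokenize(reactant_smiles), add_specials=True)], dtype=np.int64
    )
    if src.shape[1] > config.max_len:
        raise ValueError("reactant sequence exceeds max_len")
    memory, src_mask = model.encode(src)

    # each beam: (ids tuple starting with SOS, cumulative logprob, finished)
    beams: List[Tuple[Tuple[int, ...], float, bool]] = [((vocab.sos,), 0.0, False)]
    for _ in range(config.max_len - 1):
        live = [b for b in beams if not b[2]]
        if not live:
            break
        tgt = np.asarray([b[0] for b in live], dtype=np.int64)
        logp = model.next_token_logprobs(memory, src_mask, tgt)
        candidates: List[Tuple[Tuple[int, ...], float, bool]] = [
            b for b in beams if b[2]
        ]
        for (ids, score, _), row in zip(live, logp):
            # padding, start and unknown symbols are never generated, and
            # zero-probability extensions never enter the beam (candidate
            # probabilities must stay in (0, 1])
            for tok in range(len(vocab)):
                if tok in (vocab.pad, vocab.sos, vocab.unk):
                    continue
                lp = float(row[tok])
                if lp == float("-inf"):
                    continue
                candidates.append(
                    (ids + (tok,), score + lp, tok == vocab.eos)
                )
        candidates.sort(key=lambda b: (-b[1], b[0]))
        beams = candidates[: config.beam_width]
        if all(b[2] for b in beams):
            break

    results = []
    for ids, score, finished in sorted(beams, key=lambda b: (-b[1], b[0])):
        body = [i for i in ids[1:] if i != vocab.eos]
        results.append(
            BeamCandidate(
                tokens=tuple(vocab.decode(body, strip_specials=True)),
                probability=float(np.exp(score)),
                log_probability=float(score),
                finished=finished,
            )
        )
    return results


@dataclass(frozen=True)
class ProductPrediction:
    """A candidate product set after standardisation.

    ``products`` is a frozenset of standardised SMILES, or ``None`` when
    the decoded sequence failed standardisation (``valid=False``) —
    invalidity is data here, not an exception: invalid candidates are
    dropped from pathway expansion and can never match a true product
    set in evaluation.
    """

    products: Optional[frozenset]
    probability: float
    raw_smiles: str
    valid: bool


def candidates_to_product_sets(
    candidates: Sequence[BeamCandidate],
) -> List[ProductPrediction]:
    """Detokenise, split on '.', standardise each candidate.

    Duplicate standardised sets from different beams are retained here;
    deduplication is an evaluation-side decision.
    """
    out = []
    for cand in candidates:
        smiles = cand.smiles
        try:
            std = standardize(smiles)
            products: Optional[frozenset] = frozenset(std.split("."))
            valid = True
        except (InvalidSmilesError, RuleApplicationError):
            products, valid = None, False
        out.append(
            ProductPrediction(
                products=products,
                probability=cand.probability,
                raw_smiles=smiles,
                valid=valid,
            )
        )
    return out
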