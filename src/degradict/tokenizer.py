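"""SMILES tokenisation and vocabulary handling.

SMILES is tokenised with the community-standard regular expression:
mostly one token per character, but bracket atoms (``[O-]``, ``[nH]``),
two-letter halogens (``Cl``, ``Br``) and two-digit ring-bond references
(``%12``) stay single tokens.  Concatenating the tokens reproduces the
input string exactly, so detokenisation is plain ``"".join``.

Four special symbols are reserved at the bottom of every vocabulary:
padding (0), sequence start (1), sequence end (2) and unknown (3).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

__all__ = [
    "TokenizationError",
    "SMILES_TOKEN_PATTERN",
    "tokenize",
    "detokenize",
    "Vocabulary",
    "build_vocab",
    "SmilesTokenizer",
    "PAD", "SOS", "EOS", "UNK",
]

PAD, SOS, EOS, UNK = "<pad>", "<sos>", "<eos>", "<unk>"
SPECIAL_TOKENS: Tuple[str, str, str, str] = (PAD, SOS, EOS, UNK)

SMILES_TOKEN_PATTERN = (
    r"(\[[^\]]+\]|Br|Cl|N|O|S|P|F|I|B|C|b|c|n|o|s|p"
    r"|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)
_LEXER = re.compile(SMILES_TOKEN_PATTERN)


class TokenizationError(ValueError):
    """Raised when a SMILES contains a character the lexer cannot match."""


def tokenize(smiles: str) -> List[str]:
    """Split a SMILES string into lexer tokens.

    Raises :class:`TokenizationError` (with position) on any character
    not matched by the pattern, rather than silently dropping it.
    """
    tokens: List[str] = []
    pos = 0
    for match in _LEXER.finditer(smiles):
        if match.start() != pos:
            raise TokenizationError(
                f"cannot tokenise {smiles!r} at position {pos}: "
                f"{smiles[pos:match.start()]!r}"
            )
        tokens.append(match.group())
        pos = match.end()
    if pos != len(smiles):
        raise TokenizationError(
            f"cannot tokenise {smiles!r} at position {pos}: {smiles[pos:]!r}"
        )
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    """Concatenate tokens back into a SMILES string, skipping specials."""
    return "".join(t for t in tokens if t not in SPECIAL_TOKENS)


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token-to-index map with reserved special indices 0..3.

    Built deterministically from a corpus: non-special tokens are ordered
    by descending frequency, ties broken lexicographically.
    """

    token_to_index: Dict[str, int]

    def __post_init__(self):
        for i, tok in enumerate(SPECIAL_TOKENS):
            if self.token_to_index.get(tok) != i:
                raise ValueError("special tokens must occupy indices 0..3")
        rev = {i: t for t, i in self.token_to_index.items()}
        if len(rev) != len(self.token_to_index):
            raise ValueError("token_to_index must be bijective")
        object.__setattr__(self, "_index_to_token", rev)

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    @property
    def pad(self) -> int:
        return 0

    @property
    def sos(self) -> int:
        return 1

    @property
    def eos(self) -> int:
        return 2

    @property
    def unk(self) -> int:
        return 3

    def encode(self, tokens: Sequence[str], add_specials: bool = False) -> List[int]:
        ids = [self.token_to_index.get(t, self.unk) for t in tokens]
        if add_specials:
            ids = [self.sos] + ids + [self.eos]
        return ids

    def decode(self, indices: Sequence[int], strip_specials: bool = True) -> List[str]:
        toks = [self._index_to_token[int(i)] for i in indices]
        if strip_specials:
            toks = [t for t in toks if t not in SPECIAL_TOKENS]
        return toks

    def save(self, path) -> None:
        """Serialise as a two-column text file: token<TAB>index."""
        with open(path, "w") as fh:
            for tok, idx in sorted(self.token_to_index.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok}\t{idx}\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        mapping: Dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                tok, idx = line.rstrip("\n").split("\t")
                mapping[tok] = int(idx)
        return cls(mapping)

    def content_hash(self) -> str:
        import hashlib

        items = sorted(self.token_to_index.items(), key=lambda kv: kv[1])
        return hashlib.sha256(repr(items).encode()).hexdigest()[:16]


def build_vocab(corpus: Iterable[Sequence[str]]) -> Vocabulary:
    """Build a :class:`Vocabulary` from an iterable of token sequences."""
    counts: Dict[str, int] = {}
    n = 0
    for seq in corpus:
        n += 1
        for tok in seq:
            counts[tok] = counts.get(tok, 0) + 1
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    ordered = sorted(counts, key=lambda t: (-counts[t], t))
    mapping = {tok: i for i, tok in enumerate(SPECIAL_TOKENS)}
    for tok in ordered:
        if tok not in mapping:
            mapping[tok] = len(mapping)
    return Vocabulary(mapping)


class SmilesTokenizer:
    """Scikit-learn style transformer: SMILES strings -> index sequences.

    ``fit`` builds the vocabulary from the training strings; ``transform``
    encodes strings to integer id lists (with start/end symbols when
    ``add_specials``).  Sequences longer than ``max_len`` (counting the
    specials) are rejected, never truncated: a truncated SMILES is a
    different molecule.
    """

    def __init__(self, max_len: int = 276, add_specials: bool = True):
        self.max_len = max_len
        self.add_specials = add_specials

    def get_params(self, deep: bool = True) -> dict:
        return {"max_len": self.max_len, "add_specials": self.add_specials}

    def set_params(self, **params) -> "SmilesTokenizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: Sequence[str], y=None) -> "SmilesTokenizer":
        self.vocab_ = build_vocab(tokenize(s) for s in X)
        return self

    def transform(self, X: Sequence[str]) -> List[List[int]]:
        if not hasattr(self, "vocab_"):
            raise RuntimeError("SmilesTokenizer must be fitted before transform")
        out = []
        for s in X:
            ids = self.vocab_.encode(tokenize(s), add_specials=self.add_specials)
            if len(ids) > self.max_len:
                raise ValueError(
                    f"sequence of length {len(ids)} exceeds max_len={self.max_len}: "
                    f"{s[:40]!r}..."
                )
            out.append(ids)
        return out

    def fit_transform(self, X: Sequence[str], y=None) -> List[List[int]]:
        return self.fit(X).transform(X)

    def inverse_transform(self, X: Sequence[Sequence[int]]) -> List[str]:
        return [detokenize(self.vocab_.decode(ids)) for ids in X]
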