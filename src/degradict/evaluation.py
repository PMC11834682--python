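"""Reaction-level evaluation: product-set equality, Top-K, threshold
precision-recall curves, and pathway-level cross-validation splits.

Product comparison is subset-based: a prediction counts as correct when
the *actual* product set is a subset of the predicted set, so compound
order is irrelevant and predicting extra compounds is not penalised
(biodegradation datasets routinely omit co-products).

Two complementary reaction-level scores are computed from the ranked,
probability-weighted candidates:

* **Top-K** — a true reaction is a hit when any of its reactant's K most
  probable candidates matches.  The hit fraction is reported as both
  precision and recall: with a fixed K the metric cannot distinguish
  the two, which is exactly why it resembles recall far more than
  accuracy.
* **Single generation** — candidates with probability >= threshold are
  accepted; precision is the fraction of accepted candidates that match
  a true product set of their reactant, recall the fraction of true
  reactions matched by at least one accepted candidate.  Sweeping the
  threshold yields a PR curve; its AUC is the trapezoidal area over
  recall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import Reaction

__all__ = [
    "Candidate",
    "PredictionRecord",
    "EvalScores",
    "PRCurve",
    "EvalConfig",
    "products_equal",
    "topk_scores",
    "single_gen_scores",
    "pr_curve",
    "trapezoid_auc",
    "crossval_split",
    "default_threshold_grid",
]


@dataclass(frozen=True)
class Candidate:
    """One ranked candidate: standardised product set (None = invalid
    SMILES) and its sequence probability."""

    products: Optional[frozenset]
    probability: float

    @property
    def valid(self) -> bool:
        return self.products is not None


@dataclass
class PredictionRecord:
    """All predictions and truths for one reactant.

    ``true_sets`` holds one product set per true reaction sharing this
    reactant (separate reactions are never merged); ``candidates`` are
    sorted by probability descending.
    """

    reactant: str
    true_sets: List[frozenset]
    candidates: List[Candidate]

    def __post_init__(self):
        self.candidates = sorted(
            self.candidates, key=lambda c: -c.probability
        )


@dataclass(frozen=True)
class EvalScores:
    precision: float
    recall: float
    degenerate_precision: bool = False


@dataclass(frozen=True)
class PRCurve:
    """PR points (threshold, precision, recall) plus trapezoidal AUC."""

    points: Tuple[Tuple[float, float, float], ...]
    auc: float


@dataclass(frozen=True)
class EvalConfig:
    threshold: float = 0.5
    k: int = 1
    threshold_grid: Tuple[float, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        grid = tuple(self.threshold_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("threshold_grid must be strictly increasing")
        if grid and (grid[0] < 0 or grid[-1] > 1):
            raise ValueError("threshold_grid must lie within [0, 1]")


def default_threshold_grid(n: int = 101) -> Tuple[float, ...]:
    """Evenly spaced thresholds covering [0, 1]."""
    return tuple(np.linspace(0.0, 1.0, n))


def products_equal(actual: frozenset, predicted: Optional[frozenset]) -> bool:
    """True iff every actual product appears among the predictions.

    Set comparison: order-free, and extra predicted compounds are
    ignored.  An invalid prediction (``None``) never matches.
    """
    if predicted is None:
        return False
    return frozenset(actual) <= frozenset(predicted)


def _n_true(records: Sequence[PredictionRecord]) -> int:
    return sum(len(r.true_sets) for r in records)


def topk_scores(records: Sequence[PredictionRecord], k: int) -> EvalScores:
    """Hit fraction of true reactions within the top-``k`` candidates.

    Reported identically as precision and recall — the Top-K metric has
    no separate notion of the two.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    total = _n_true(records)
    if total == 0:
        return EvalScores(1.0, 1.0, degenerate_precision=True)
    hits = 0
    for rec in records:
        top = rec.candidates[:k]
        for true_set in rec.true_sets:
            if any(products_equal(true_set, c.products) for c in top):
                hits += 1
    frac = hits / total
    return EvalScores(frac, frac)


def _dedupe(candidates: Sequence[Candidate]) -> List[Candidate]:
    """Collapse identical standardised product sets, keeping max probability.

    Beams frequently collapse to the same molecule set after
    standardisation; counting them once keeps precision meaningful.
    Invalid candidates carry no product set and are kept as-is.
    """
    best: Dict[frozenset, float] = {}
    invalid: List[Candidate] = []
    for c in candidates:
        if c.products is None:
            invalid.append(c)
        elif c.products not in best or c.probability > best[c.products]:
            best[c.products] = c.probability
    deduped = [Candidate(p, prob) for p, prob in best.items()] + invalid
    return sorted(deduped, key=lambda c: -c.probability)


def single_gen_scores(
    records: Sequence[PredictionRecord], threshold: float
) -> EvalScores:
    """Threshold-based precision/recall over individual reactions.

    Candidates with probability >= threshold are accepted (deduplicated
    per reactant first).  Invalid-SMILES candidates count as accepted
    non-matches — the model did positively predict them — but can never
    match.  With zero accepted candidates precision is undefined and
    reported as 1.0 with ``degenerate_precision`` set.
    """
    accepted_total = 0
    accepted_matching = 0
    true_matched = 0
    for rec in records:
        accepted = [
            c for c in _dedupe(rec.candidates) if c.probability >= threshold
        ]
        accepted_total += len(accepted)
        for c in accepted:
            if any(products_equal(t, c.products) for t in rec.true_sets):
                accepted_matching += 1
        for t in rec.true_sets:
            if any(products_equal(t, c.products) for c in accepted):
                true_matched += 1
    total_true = _n_true(records)
    recall = true_matched / total_true if total_true else 0.0
    if accepted_total == 0:
        return EvalScores(1.0, recall, degenerate_precision=True)
    return EvalScores(accepted_matching / accepted_total, recall)


def trapezoid_auc(points: Sequence[Tuple[float, float]]) -> float:
    """Trapezoidal area under (recall, precision) points.

    Points are sorted by recall ascending; no extrapolation to recall
    0 or 1 is performed, so the value reflects only the achieved range.
    """
    if len(points) < 2:
        # a single point has no extent; its rectangle precision*recall is
        # the documented degenerate contract
        if len(points) == 1:
            r, p = points[0]
            return float(r * p)
        return 0.0
    pts = sorted(points)
    r = np.array([q[0] for q in pts])
    p = np.array([q[1] for q in pts])
    return float(np.trapezoid(p, r))


def pr_curve(
    records: Sequence[PredictionRecord],
    config: EvalConfig,
) -> PRCurve:
    """One (precision, recall) point per grid threshold, plus AUC."""
    grid = config.threshold_grid or default_threshold_grid()
    points = []
    for thr in grid:
        s = single_gen_scores(records, thr)
        points.append((float(thr), s.precision, s.recall))
    auc = trapezoid_auc([(r, p) for _, p, r in points])
    return PRCurve(points=tuple(points), auc=auc)


def crossval_split(
    pathways: Sequence,
    k: int = 10,
    seed: int = 0,
) -> List[Tuple[List[Reaction], List[Reaction], List]]:
    """K-fold cross-validation split **on pathways**, with leakage removal.

    Pathways are shuffled (seeded) and partitioned into ``k`` folds; each
    fold in turn supplies the test pathways while the remaining folds'
    reactions form the training set.  Because different pathways can
    contain the same reactions, any training reaction whose reactant
    string appears as a test-set reactant, or whose product string
    appears as a test-set product, is removed (whole-side dot-joined
    string comparison).

    Returns ``k`` tuples ``(train_reactions, test_reactions,
    test_pathways)``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(pathways) < k:
        raise ValueError(f"need at least k={k} pathways, got {len(pathways)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pathways))
    folds = [list(order[i::k]) for i in range(k)]
    splits = []
    for i in range(k):
        test_paths = [pathways[j] for j in folds[i]]
        train_paths = [pathways[j] for f in range(k) if f != i for j in folds[f]]
        test_reactions = [rx for p in test_paths for rx in p.reactions]
        train_reactions = [rx for p in train_paths for rx in p.reactions]
        test_reactants = {rx.reactant_smiles for rx in test_reactions}
        test_products = {rx.product_smiles for rx in test_reactions}
        train_reactions = [
            rx
            for rx in train_reactions
            if rx.reactant_smiles not in test_reactants
            and rx.product_smiles not in test_products
        ]
        splits.append((train_reactions, test_reactions, test_paths))
    return splits
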