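"""Recursive pathway prediction and depth-weighted pathway scoring.

A biodegradation pathway is a rooted directed acyclic graph: the root
compound degrades into products, which degrade further.  Prediction
expands the graph breadth-first, re-decoding every retained product,
pruned by the *conditional probability* of a node — the product of the
model's edge probabilities from the root — falling below a threshold.

Pathway scoring weights a compound at depth ``d`` by ``1/2^d``: early
degradation steps are both more certain in the data and more important
to get right.  Predicted compounds that merely sit *between* a matched
parent and a matched true product ("intermediates") are score-neutral,
reflecting that true pathways routinely omit short-lived intermediates;
an unmatched predicted compound is an error weighted by its collapsed
depth, i.e. counting only non-intermediate ancestors — so an error deep
in the prediction hurts less than one at the first generation.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .chem import InvalidSmilesError, Reaction, standardize
from .decoding import DecodeConfig, beam_decode, candidates_to_product_sets
from .evaluation import EvalScores, PRCurve, trapezoid_auc

__all__ = [
    "Pathway",
    "MultiGenConfig",
    "predict_pathway",
    "multigen_scores",
    "multigen_curve",
]


@dataclass(frozen=True)
class MultiGenConfig:
    """Pathway-prediction settings.

    ``max_depth`` 7 matches the evaluation profile; the faster runtime
    profile uses depth 4 with at most 3 children per node.  ``max_width``
    ``None`` leaves the per-node branching limited only by the beam.
    The threshold applies to the root-conditional probability and is the
    same single value at every depth — deeper nodes are pruned naturally
    because conditional probabilities can only shrink along a path.
    """

    threshold: float = 0.5
    max_depth: int = 7
    max_width: Optional[int] = None
    beam_width: int = 5

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.max_width is not None and self.max_width < 1:
            raise ValueError("max_width must be >= 1 or None")


class Pathway:
    """Rooted DAG of compounds; edges are degradation reactions.

    Nodes are keyed by their standardised SMILES.  Each node carries
    ``depth`` (shortest edge-count from the root) and, for predicted
    pathways, ``conditional_probability`` (product of edge probabilities
    from the root).  ``reactions`` optionally carries the constituent
    reaction objects (used for training-set extraction in
    cross-validation).
    """

    def __init__(
        self,
        root: str,
        graph: Optional[nx.DiGraph] = None,
        reactions: Optional[List[Reaction]] = None,
    ):
        self.graph = graph if graph is not None else nx.DiGraph()
        if root not in self.graph:
            self.graph.add_node(root)
        self.root = root
        self.reactions = reactions if reactions is not None else []
        self._recompute_depths()

    # ------------------------------------------------------------ structure
    def add_edge(self, parent: str, child: str, probability: Optional[float] = None):
        if parent not in self.graph:
            raise ValueError(f"unknown parent node {parent!r}")
        self.graph.add_edge(parent, child)
        if probability is not None:
            self.graph.edges[parent, child]["probability"] = float(probability)
        self._recompute_depths()

    def _recompute_depths(self) -> None:
        depths = nx.single_source_shortest_path_length(self.graph, self.root)
        if set(depths) != set(self.graph.nodes):
            unreachable = set(self.graph.nodes) - set(depths)
            raise ValueError(f"nodes unreachable from root: {sorted(unreachable)!r}")
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("pathway must be acyclic")
        nx.set_node_attributes(self.graph, depths, "depth")

    def depth(self, node: str) -> int:
        return self.graph.nodes[node]["depth"]

    @property
    def nodes(self) -> List[str]:
        return list(self.graph.nodes)

    def children(self, node: str) -> List[str]:
        return sorted(self.graph.successors(node))

    def conditional_probability(self, node: str) -> float:
        return self.graph.nodes[node].get("conditional_probability", 1.0)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    # ---------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "nodes": [
                {
                    "id": n,
                    "smiles": n,
                    "depth": self.depth(n),
                    **(
                        {
                            "conditional_probability": self.graph.nodes[n][
                                "conditional_probability"
                            ]
                        }
                        if "conditional_probability" in self.graph.nodes[n]
                        else {}
                    ),
                }
                for n in self.graph.nodes
            ],
            "edges": [
                {
                    "parent": u,
                    "child": v,
                    **(
                        {"probability": d["probability"]}
                        if "probability" in d
                        else {}
                    ),
                }
                for u, v, d in self.graph.edges(data=True)
            ],
            "reactions": [r.to_smiles() for r in self.reactions],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Pathway":
        g = nx.DiGraph()
        for node in data["nodes"]:
            g.add_node(node["smiles"])
            if "conditional_probability" in node:
                g.nodes[node["smiles"]]["conditional_probability"] = node[
                    "conditional_probability"
                ]
        for edge in data["edges"]:
            g.add_edge(edge["parent"], edge["child"])
            if "probability" in edge:
                g.edges[edge["parent"], edge["child"]]["probability"] = edge[
                    "probability"
                ]
        reactions = [Reaction.from_smiles(s) for s in data.get("reactions", [])]
        return cls(root=data["root"], graph=g, reactions=reactions)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Pathway":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dot(self) -> str:
        """GraphViz DOT text for eyeballing a pathway."""
        lines = ["digraph pathway {"]
        for n in self.graph.nodes:
            label = n
            if "conditional_probability" in self.graph.nodes[n]:
                label += f"\\np={self.graph.nodes[n]['conditional_probability']:.3f}"
            shape = "doubleoctagon" if n == self.root else "box"
            lines.append(f'  "{n}" [label="{label}", shape={shape}];')
        for u, v, d in self.graph.edges(data=True):
            attr = f' [label="{d["probability"]:.2f}"]' if "probability" in d else ""
            lines.append(f'  "{u}" -> "{v}"{attr};')
        lines.append("}")
        return "\n".join(lines)


def predict_pathway(estimator, root: str, config: MultiGenConfig) -> Pathway:
    """Recursively predict a degradation pathway from a root compound.

    Breadth-first: every frontier compound is beam-decoded; each valid
    candidate product set contributes its compounds as children with
    conditional probability = parent's x candidate's.  Children falling
    below ``config.threshold`` are pruned, invalid-SMILES candidates are
    dropped, compounds already present in the pathway are not duplicated,
    and with ``max_width`` set only the most probable children of each
    node are kept.  Expansion stops at ``max_depth`` or an empty frontier.
    """
    try:
        root_std = standardize(root)
    except InvalidSmilesError as exc:
        raise InvalidSmilesError(f"invalid root compound: {root!r}") from exc
    pathway = Pathway(root=root_std)
    pathway.graph.nodes[root_std]["conditional_probability"] = 1.0
    decode_cfg = DecodeConfig(beam_width=config.beam_width)
    frontier = deque([root_std])
    while frontier:
        parent = frontier.popleft()
        depth = pathway.depth(parent)
        if depth >= config.max_depth:
            continue
        parent_prob = pathway.conditional_probability(parent)
        candidates = candidates_to_product_sets(
            beam_decode(estimator, parent, decode_cfg)
        )
        # deduplicate identical product sets, keep max probability
        best: Dict[frozenset, float] = {}
        for cand in candidates:
            if not cand.valid:
                continue
            if cand.products not in best or cand.probability > best[cand.products]:
                best[cand.products] = cand.probability
        children: List[Tuple[str, float]] = []
        for products, prob in best.items():
            cond = parent_prob * prob
            if cond < config.threshold:
                continue
            for compound in sorted(products):
                children.append((compound, prob))
        children.sort(key=lambda cp: (-cp[1], cp[0]))
        if config.max_width is not None:
            children = children[: config.max_width]
        for compound, prob in children:
            if compound in pathway.graph:
                continue  # keep the prediction a tree; first (shallowest) wins
            pathway.graph.add_node(
                compound, conditional_probability=parent_prob * prob
            )
            pathway.graph.add_edge(parent, compound, probability=prob)
            frontier.append(compound)
        pathway._recompute_depths()
    return pathway


def _compound(pathway: Pathway, node: str) -> str:
    return node  # nodes are keyed by standardised SMILES


def multigen_scores(true: Pathway, predicted: Pathway) -> EvalScores:
    """Depth-weighted precision/recall of a predicted pathway.

    Matching proceeds top-down from the shared root.  For a true node
    matched at predicted node ``p``, each true child is searched for
    among the unclaimed descendants of ``p`` breadth-first (nearest
    first); predicted nodes strictly between ``p`` and the match are
    intermediates and score-neutral.  A matched true node contributes
    ``1/2^d`` with ``d`` its depth in the *true* pathway (so a product
    found via intermediates is scored as if it were an immediate child).
    Unmatched, non-intermediate predicted nodes are errors weighted by
    their collapsed depth (counting only non-intermediate ancestors).

    recall = matched weight / total true weight (root excluded);
    precision = matched weight / (matched + error weight), reported as
    1.0 with the degenerate flag when nothing was predicted at all.
    """
    if true.root != predicted.root:
        raise ValueError(
            f"root mismatch: true {true.root!r} vs predicted {predicted.root!r}"
        )
    claimed: Dict[str, str] = {}  # predicted node -> matched true node
    intermediates: Set[str] = set()
    matched_weight = 0.0

    queue: deque = deque([(true.root, predicted.root)])
    while queue:
        t_node, p_node = queue.popleft()
        for t_child in true.children(t_node):
            q = _find_match(predicted, p_node, t_child, claimed)
            if q is None:
                continue
            q_node, between = q
            claimed[q_node] = t_child
            intermediates.update(between)
            matched_weight += 0.5 ** true.depth(t_child)
            queue.append((t_child, q_node))

    total_true_weight = sum(
        0.5 ** true.depth(n) for n in true.nodes if n != true.root
    )
    error_weight = 0.0
    for n in predicted.nodes:
        if n == predicted.root or n in claimed or n in intermediates:
            continue
        error_weight += 0.5 ** _collapsed_depth(predicted, n, intermediates)

    recall = matched_weight / total_true_weight if total_true_weight else 1.0
    denom = matched_weight + error_weight
    if denom == 0.0:  # no scored predictions at all (e.g. root-only)
        return EvalScores(1.0, recall, degenerate_precision=True)
    return EvalScores(matched_weight / denom, recall)


def _find_match(
    predicted: Pathway, start: str, target_compound: str, claimed: Dict[str, str]
) -> Optional[Tuple[str, List[str]]]:
    """Nearest unclaimed descendant of ``start`` whose compound matches.

    Returns the matching node and the nodes strictly between ``start``
    and it (the intermediates), or None.
    """
    visited = {start}
    queue = deque([(child, []) for child in predicted.children(start)])
    while queue:
        node, between = queue.popleft()
        if node in visited:
            continue
        visited.add(node)
        if node not in claimed and _compound(predicted, node) == target_compound:
            return node, between
        queue.extend(
            (child, between + [node]) for child in predicted.children(node)
        )
    return None


def _collapsed_depth(pathway: Pathway, node: str, intermediates: Set[str]) -> int:
    """Depth counting only non-intermediate ancestors on a shortest path."""
    path = nx.shortest_path(pathway.graph, pathway.root, node)
    return sum(1 for n in path[1:-1] if n not in intermediates) + 1


def multigen_curve(
    estimator,
    true_pathways: Sequence[Pathway],
    thresholds: Sequence[float],
    config: Optional[MultiGenConfig] = None,
) -> PRCurve:
    """PR curve over pathway predictions at each threshold.

    Per threshold, every true pathway's root is expanded with
    :func:`predict_pathway` and scored; precision and recall are the
    unweighted means over pathways.
    """
    base = config or MultiGenConfig()
    points = []
    for thr in thresholds:
        cfg = MultiGenConfig(
            threshold=thr,
            max_depth=base.max_depth,
            max_width=base.max_width,
            beam_width=base.beam_width,
        )
        precisions, recalls = [], []
        for true in true_pathways:
            predicted = predict_pathway(estimator, true.root, cfg)
            scores = multigen_scores(true, predicted)
            precisions.append(scores.precision)
            recalls.append(scores.recall)
        points.append(
            (float(thr), float(sum(precisions) / len(precisions)),
             float(sum(recalls) / len(recalls)))
        )
    auc = trapezoid_auc([(r, p) for _, p, r in points])
    return PRCurve(points=tuple(points), auc=auc)
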