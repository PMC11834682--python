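"""Pathway prediction and depth-weighted pathway scoring."""

import networkx as nx
import pytest

import degradict as dd
from degradict.pathway import (
    MultiGenConfig,
    Pathway,
    multigen_curve,
    multigen_scores,
    predict_pathway,
)

A, B, C, D, E, F = ("C" * (i + 1) for i in range(6))
ROOT = "C" * 7


def chain_pathway(*compounds, probs=None):
    pw = Pathway(root=compounds[0])
    if probs is None:
        probs = [None] * (len(compounds) - 1)
    pw.graph.nodes[compounds[0]]["conditional_probability"] = 1.0
    for parent, child, p in zip(compounds, compounds[1:], probs):
        cond = pw.conditional_probability(parent) * (p if p is not None else 1.0)
        pw.graph.add_node(child, conditional_probability=cond)
        pw.graph.add_edge(parent, child, **({} if p is None else {"probability": p}))
    pw._recompute_depths()
    return pw


class TestPathwayStructure:
    def test_depth_is_shortest_path(self):
        pw = Pathway(root=A)
        pw.add_edge(A, B)
        pw.add_edge(B, C)
        pw.add_edge(A, C)  # converging: C reachable directly
        assert pw.depth(C) == 1

    def test_cycle_rejected(self):
        pw = Pathway(root=A)
        pw.add_edge(A, B)
        with pytest.raises(ValueError):
            pw.add_edge(B, A)

    def test_unreachable_node_rejected(self):
        g = nx.DiGraph()
        g.add_node(A)
        g.add_node(B)
        with pytest.raises(ValueError):
            Pathway(root=A, graph=g)

    def test_json_round_trip(self, tmp_path):
        true, predicted = dd.fig6_fixture()
        path = tmp_path / "pw.json"
        predicted.to_json(path)
        loaded = Pathway.from_json(path)
        assert loaded.root == predicted.root
        assert set(loaded.nodes) == set(predicted.nodes)
        assert set(loaded.graph.edges) == set(predicted.graph.edges)
        for n in predicted.nodes:
            assert loaded.conditional_probability(n) == pytest.approx(
                predicted.conditional_probability(n)
            )

    def test_dot_export_mentions_all_nodes(self):
        true, _ = dd.fig6_fixture()
        dot = true.to_dot()
        for n in true.nodes:
            assert f'"{n}"' in dot


class TestMultiGenScores:
    def test_printed_worked_example(self):
        true, predicted = dd.fig6_fixture()
        s = multigen_scores(true, predicted)
        assert s.precision == pytest.approx(1.0)
        assert s.recall == pytest.approx(0.75)

    def test_identical_pathways_perfect(self):
        true, _ = dd.fig6_fixture()
        s = multigen_scores(true, true)
        assert (s.precision, s.recall) == (1.0, 1.0)

    def test_root_only_prediction(self):
        true, _ = dd.fig6_fixture()
        s = multigen_scores(true, Pathway(root=true.root))
        assert s.recall == 0.0
        assert s.precision == 1.0 and s.degenerate_precision

    def test_root_mismatch_rejected(self):
        true, _ = dd.fig6_fixture()
        with pytest.raises(ValueError, match="root"):
            multigen_scores(true, Pathway(root=E))

    def test_intermediate_insertion_does_not_change_scores(self):
        """A score-neutral intermediate on a predicted chain leaves both
        recall and precision unchanged when the final compound matches."""
        true = chain_pathway(ROOT, B, D)
        direct = chain_pathway(ROOT, B, D)
        via_intermediate = chain_pathway(ROOT, B, F, D)
        s1 = multigen_scores(true, direct)
        s2 = multigen_scores(true, via_intermediate)
        assert s1.precision == s2.precision == 1.0
        assert s1.recall == s2.recall

    def test_deeper_error_hurts_less(self):
        true = chain_pathway(ROOT, B)
        shallow_error = chain_pathway(ROOT, B)
        shallow_error.add_edge(ROOT, E)  # error at depth 1: weight 1/2
        deep_error = chain_pathway(ROOT, B)
        deep_error.add_edge(B, E)  # error at depth 2: weight 1/4
        p_shallow = multigen_scores(true, shallow_error).precision
        p_deep = multigen_scores(true, deep_error).precision
        assert p_deep > p_shallow
        assert p_shallow == pytest.approx(0.5 / (0.5 + 0.5))
        assert p_deep == pytest.approx(0.5 / (0.5 + 0.25))

    def test_error_below_intermediate_uses_collapsed_depth(self):
        # predicted root -> B -> F -> D with true D matched at depth 2 via
        # intermediate F; an extra error child under D collapses to depth 3
        true = chain_pathway(ROOT, B, D)
        predicted = chain_pathway(ROOT, B, F, D, E)
        s = multigen_scores(true, predicted)
        # matched: B (1/2) + D (1/4); error E at collapsed depth 3 (1/8)
        assert s.precision == pytest.approx((0.5 + 0.25) / (0.5 + 0.25 + 0.125))
        assert s.recall == 1.0


class TestPredictPathway:
    def test_threshold_one_keeps_root_only(self, fake_estimator_factory):
        est = fake_estimator_factory({A: {B: 0.6, C: 0.3}})
        pw = predict_pathway(est, A, MultiGenConfig(threshold=1.0, max_depth=3))
        assert pw.nodes == [A]

    def test_certain_chain_reaches_max_depth(self, fake_estimator_factory):
        est = fake_estimator_factory(
            {A: {B: 1.0}, B: {C: 1.0}, C: {D: 1.0}, D: {E: 1.0}, E: {F: 1.0}}
        )
        pw = predict_pathway(est, A, MultiGenConfig(threshold=0.5, max_depth=3))
        assert set(pw.nodes) == {A, B, C, D}
        assert all(
            pw.conditional_probability(n) == pytest.approx(1.0) for n in pw.nodes
        )

    def test_conditional_probability_pruning(self, fake_estimator_factory):
        """With 0.6/0.3 children everywhere and threshold 0.2, the 0.36
        grandchild survives and the 0.18 one is pruned."""
        est = fake_estimator_factory(
            {
                A: {B: 0.6, C: 0.3},
                B: {D: 0.6, E: 0.3},
                C: {F: 0.6, ROOT: 0.3},
                D: {"C" * 8: 0.6},
            }
        )
        pw = predict_pathway(est, A, MultiGenConfig(threshold=0.2, max_depth=2))
        assert set(pw.nodes) == {A, B, C, D}
        assert pw.conditional_probability(D) == pytest.approx(0.36)
        assert E not in pw.graph  # 0.6 * 0.3 = 0.18 < 0.2
        assert F not in pw.graph  # 0.3 * 0.6 = 0.18 < 0.2

    def test_multi_product_candidate_adds_all_compounds(self, fake_estimator_factory):
        est = fake_estimator_factory({A: {f"{B}.{C}": 0.9}})
        pw = predict_pathway(est, A, MultiGenConfig(threshold=0.5, max_depth=1))
        assert set(pw.nodes) == {A, B, C}
        assert pw.conditional_probability(B) == pytest.approx(0.9)
        assert pw.conditional_probability(C) == pytest.approx(0.9)

    def test_invalid_candidates_are_dropped(self, fake_estimator_factory):
        est = fake_estimator_factory({A: {"C(C": 0.9, B: 0.1}})
        pw = predict_pathway(
            est, A, MultiGenConfig(threshold=0.05, max_depth=1, beam_width=2)
        )
        assert set(pw.nodes) == {A, B}

    def test_max_width_limits_children(self, fake_estimator_factory):
        est = fake_estimator_factory(
            {A: {B: 0.3, C: 0.25, D: 0.2, E: 0.15}}
        )
        pw = predict_pathway(
            est, A, MultiGenConfig(threshold=0.01, max_depth=1, max_width=3,
                                   beam_width=8)
        )
        assert set(pw.nodes) == {A, B, C, D}

    def test_conditional_probabilities_nonincreasing_along_paths(
        self, fake_estimator_factory
    ):
        est = fake_estimator_factory(
            {A: {B: 0.8, C: 0.5}, B: {D: 0.9}, C: {E: 0.9}, D: {F: 0.9}}
        )
        pw = predict_pathway(est, A, MultiGenConfig(threshold=0.1, max_depth=4))
        for u, v in pw.graph.edges:
            assert pw.conditional_probability(v) <= pw.conditional_probability(u) + 1e-12

    def test_invalid_root_rejected(self, fake_estimator_factory):
        est = fake_estimator_factory({A: {B: 1.0}})
        with pytest.raises(dd.InvalidSmilesError):
            predict_pathway(est, "C(C", MultiGenConfig())

    def test_node_count_bounded_by_beam_geometry(self, trained_estimator):
        cfg = MultiGenConfig(threshold=0.05, max_depth=3, beam_width=3)
        pw = predict_pathway(trained_estimator, "CCCCCCCl", cfg)
        bound = sum(3 ** i for i in range(cfg.max_depth + 1))
        assert 1 <= len(pw) <= bound


class TestMultiGenCurve:
    def test_single_threshold_on_worked_example_model(self, fake_estimator_factory):
        # a model that reproduces the fig6 predicted pathway exactly
        est = fake_estimator_factory(
            {ROOT: {B: 0.9}, B: {F: 0.8}, F: {D: 0.7}, D: {E: 0.01}}
        )
        true, _ = dd.fig6_fixture()
        curve = multigen_curve(
            est, [true], thresholds=[0.3],
            config=MultiGenConfig(max_depth=7, beam_width=2),
        )
        thr, precision, recall = curve.points[0]
        assert precision == pytest.approx(1.0)
        assert recall == pytest.approx(0.75)

    def test_threshold_above_all_probabilities_gives_zero_recall(
        self, fake_estimator_factory
    ):
        est = fake_estimator_factory({A: {B: 0.6}, B: {C: 0.6}})
        true = chain_pathway(A, B, C)
        curve = multigen_curve(est, [true], thresholds=[0.99])
        assert curve.points[0][2] == 0.0
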