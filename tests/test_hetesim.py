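"""HeteSim: transition operators, matrix vs brute-force agreement, and the
score's defining properties (range, symmetry, self-relevance)."""

import math

import numpy as np
import pytest

from hetepath import (
    ConceptNode,
    KnowledgeGraph,
    Predication,
    aggregate_hetesim,
    hetesim_brute_force,
    hetesim_profile,
    hetesim_score,
    parse_metapath,
    transition_operator,
)
from hetepath.metapaths import FORWARD, MetaPath, MetaPathStep

from .conftest import (
    D1,
    D2,
    DISEASE,
    build_g1,
    random_graph,
    random_metapath_with_instance,
)


def _mini_graph(edges, nodes):
    g = KnowledgeGraph()
    for cui, name, st in nodes:
        g.add_node(ConceptNode(cui, name, st))
    for s, p, o, *count in edges:
        g.add_edge(Predication(s, p, o, support_count=count[0] if count else 1))
    return g


class TestTransitionOperator:
    STEP = MetaPathStep("PHSU", "AFFECTS", "GNGM", FORWARD)

    def test_uniform_rows(self, g1):
        op = transition_operator(g1, self.STEP)
        row = op.matrix[op.from_nodes.index(D1)].toarray().ravel()
        assert dict(zip(op.to_nodes, row)) == {"C9000011": 0.5, "C9000012": 0.5}

    def test_rows_are_stochastic_or_zero(self, g1):
        op = transition_operator(g1, self.STEP)
        sums = np.asarray(op.matrix.sum(axis=1)).ravel()
        assert all(abs(s - 1) < 1e-12 or s == 0 for s in sums)

    def test_weighted_rows_proportional_to_support(self):
        g = _mini_graph(
            [("C9000001", "AFFECTS", "C9000011", 3), ("C9000001", "AFFECTS", "C9000012", 1)],
            [("C9000001", "a", "PHSU"), ("C9000011", "b", "GNGM"), ("C9000012", "c", "GNGM")],
        )
        op = transition_operator(g, self.STEP, weighted=True)
        row = op.matrix[0].toarray().ravel()
        assert dict(zip(op.to_nodes, row)) == {"C9000011": 0.75, "C9000012": 0.25}

    def test_zero_edge_relation_warns(self, g1, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            op = transition_operator(g1, MetaPathStep("PHSU", "TREATS", "DSYN", FORWARD))
        assert op.matrix.nnz == 0
        assert any("no edges" in r.message for r in caplog.records)

    def test_missing_semtype_is_error(self, g1):
        with pytest.raises(ValueError, match="no nodes"):
            transition_operator(g1, MetaPathStep("TOPP", "TREATS", "DSYN", FORWARD))


class TestToyGraphScores:
    def test_shared_midpoint_profile_scores_one(self, g1, g1_mp):
        assert hetesim_score(g1, D1, DISEASE, g1_mp).value == pytest.approx(1.0, abs=1e-12)

    def test_partial_overlap_scores_inverse_sqrt2(self, g1, g1_mp):
        assert hetesim_score(g1, D2, DISEASE, g1_mp).value == pytest.approx(
            1 / math.sqrt(2), abs=1e-12
        )

    def test_no_instance_scores_zero(self, g1):
        mp = parse_metapath("PHSU-[TREATS>]-DSYN")
        assert hetesim_score(g1, D1, DISEASE, mp).value == 0.0

    def test_palindromic_self_relevance_is_one(self, g1, g1_mp):
        loop = MetaPath(g1_mp.steps[:1]).concat(MetaPath(g1_mp.steps[:1]).reversed())
        for s in (D1, D2):
            assert hetesim_score(g1, s, s, loop).value == pytest.approx(1.0, abs=1e-12)

    def test_type_mismatch_raises(self, g1, g1_mp):
        with pytest.raises(ValueError):
            hetesim_score(g1, DISEASE, D1, g1_mp)


class TestOddLengthPaths:
    def test_length_one_edge_midpoint(self):
        # d1 affects both genes, d2 only g1; target gene g1 receives from both
        g = build_g1()
        mp = parse_metapath("PHSU-[AFFECTS>]-GNGM")
        v1 = hetesim_score(g, D1, "C9000011", mp).value
        v2 = hetesim_score(g, D2, "C9000011", mp).value
        # d2's single edge concentrates all mass on (d2,g1); d1 splits
        assert v2 > v1 > 0
        b1 = hetesim_brute_force(g, D1, "C9000011", mp).value
        b2 = hetesim_brute_force(g, D2, "C9000011", mp).value
        assert v1 == pytest.approx(b1, abs=1e-12)
        assert v2 == pytest.approx(b2, abs=1e-12)

    @pytest.mark.parametrize("length", [1, 3])
    @pytest.mark.parametrize("seed", range(10))
    def test_matrix_matches_brute_force(self, seed, length):
        g = random_graph(seed, n_nodes=20, n_edges=45)
        sample = random_metapath_with_instance(g, seed + 31 * length, length)
        if sample is None:
            pytest.skip("no walk")
        s, t, mp = sample
        assert hetesim_score(g, s, t, mp).value == pytest.approx(
            hetesim_brute_force(g, s, t, mp).value, abs=1e-9
        )


class TestProperties:
    @pytest.mark.parametrize("seed", range(15))
    def test_range_and_reversal_symmetry(self, seed):
        g = random_graph(seed, n_nodes=25, n_edges=55)
        for length in (1, 2, 3):
            sample = random_metapath_with_instance(g, 7 * seed + length, length)
            if sample is None:
                continue
            s, t, mp = sample
            v = hetesim_score(g, s, t, mp).value
            assert 0.0 <= v <= 1.0
            assert hetesim_score(g, t, s, mp.reversed()).value == pytest.approx(v, abs=1e-12)

    def test_disconnected_pair_zero_both_implementations(self):
        g = _mini_graph(
            [("C9000001", "AFFECTS", "C9000011")],
            [
                ("C9000001", "a", "PHSU"),
                ("C9000002", "b", "PHSU"),
                ("C9000011", "g", "GNGM"),
                ("C9000021", "D", "DSYN"),
            ],
        )
        mp = parse_metapath("PHSU-[AFFECTS>]-GNGM-[ASSOCIATED_WITH>]-DSYN")
        assert hetesim_score(g, "C9000002", "C9000021", mp).value == 0.0
        assert hetesim_brute_force(g, "C9000002", "C9000021", mp).value == 0.0

    def test_added_shared_midpoint_never_decreases_length2_score(self):
        # monotone sanity: a new gene affected by s and associated with t can
        # only align the midpoint distributions further
        base_nodes = [
            ("C9000001", "s", "PHSU"),
            ("C9000011", "g1", "GNGM"),
            ("C9000012", "g2", "GNGM"),
            ("C9000013", "g3", "GNGM"),
            ("C9000021", "t", "DSYN"),
        ]
        base_edges = [
            ("C9000001", "AFFECTS", "C9000011"),
            ("C9000011", "ASSOCIATED_WITH", "C9000021"),
            ("C9000012", "ASSOCIATED_WITH", "C9000021"),
        ]
        mp = parse_metapath("PHSU-[AFFECTS>]-GNGM-[ASSOCIATED_WITH>]-DSYN")
        before = hetesim_score(
            _mini_graph(base_edges, base_nodes), "C9000001", "C9000021", mp
        ).value
        extended = base_edges + [
            ("C9000001", "AFFECTS", "C9000012"),
        ]
        after = hetesim_score(
            _mini_graph(extended, base_nodes), "C9000001", "C9000021", mp
        ).value
        assert after >= before - 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_profile_matches_per_node_scores(self, seed):
        g = random_graph(seed, n_nodes=20, n_edges=45)
        sample = random_metapath_with_instance(g, seed + 77, 2)
        if sample is None:
            pytest.skip("no walk")
        _, t, mp = sample
        profile = hetesim_profile(g, t, mp)
        for s in g.nodes_of_semtype(mp.source_semtype):
            assert profile[s] == pytest.approx(
                hetesim_score(g, s, t, mp).value, abs=1e-9
            )


class TestAggregate:
    def test_mean_over_metapaths(self, g1, g1_mp):
        other = parse_metapath("PHSU-[TREATS>]-DSYN")  # no instances: scores 0
        agg = aggregate_hetesim(g1, D1, [DISEASE], [g1_mp, other])
        assert agg.value == pytest.approx(0.5, abs=1e-12)

    def test_mean_over_targets(self):
        # two targets wired identically to d1 -> per-target scores 1.0 and 1.0
        g = build_g1()
        g.add_node(ConceptNode("C9000022", "D2", "DSYN"))
        g.add_edge(Predication("C9000011", "ASSOCIATED_WITH", "C9000022"))
        mp = parse_metapath("PHSU-[AFFECTS>]-GNGM-[ASSOCIATED_WITH>]-DSYN")
        agg = aggregate_hetesim(g, D2, [DISEASE, "C9000022"], [mp])
        expected = (1 / math.sqrt(2) + 1.0) / 2
        assert agg.value == pytest.approx(expected, abs=1e-12)

    def test_all_instance_free_is_zero(self, g1):
        mp = parse_metapath("PHSU-[TREATS>]-DSYN")
        assert aggregate_hetesim(g1, D1, [DISEASE], [mp]).value == 0.0

    def test_empty_metapath_list_is_error(self, g1):
        with pytest.raises(ValueError):
            aggregate_hetesim(g1, D1, [DISEASE], [])
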