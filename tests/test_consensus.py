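"""Consensus stage: agreements, supernodes, merging, ranking, correlation."""

import pytest

from unicent import (
    DiscoveryTrace,
    SignedNetwork,
    Supernode,
    expanded_rank_vector,
    find_supernodes,
    consensus_ranking,
    merge_supernodes,
    rank_elements,
    spearman,
    universal_agreements,
)
from unicent.synthetic import GeneratorSpec, generate

from conftest import make_random_network


def trace(name, *nodes):
    return DiscoveryTrace(name, list(nodes), [set() for _ in nodes])


def sn(*groups):
    """Supernode from (members, covered) pairs given as iterables."""
    return Supernode.build([(frozenset(m), frozenset(c)) for m, c in groups])


class TestUniversalAgreements:
    def test_intersection(self):
        traces = [trace("BET", "a", "b"), trace("CLO", "b", "c"), trace("DEG", "b")]
        assert universal_agreements(traces) == {"b"}

    def test_identical_sets_agree_entirely(self):
        traces = [trace(n, "x", "y") for n in ("BET", "CLO", "DEG")]
        assert universal_agreements(traces) == {"x", "y"}

    def test_disjoint_sets_agree_on_nothing(self):
        assert universal_agreements([trace("BET", "a"), trace("CLO", "b")]) == set()

    def test_fewer_than_two_traces_rejected(self):
        with pytest.raises(ValueError):
            universal_agreements([trace("BET", "a")])
        with pytest.raises(ValueError):
            universal_agreements([trace("BET", "a"), trace("BET", "b")])


class TestFindSupernodes:
    def test_triangle_covered_once_per_backbone(self):
        g = SignedNetwork([("x", "y", 0.5), ("y", "z", 0.5), ("x", "z", 0.5)])
        traces = [trace("BET", "x"), trace("CLO", "y"), trace("DEG", "z")]
        found = find_supernodes(g, traces, set())
        assert len(found) == 1
        assert found[0].positions == (
            frozenset({"x"}), frozenset({"y"}), frozenset({"z"})
        )

    def test_adjacent_pair_with_double_coverage(self):
        g = SignedNetwork([("x", "y", 0.5)])
        traces = [trace("BET", "x"), trace("CLO", "y"), trace("DEG", "y")]
        found = find_supernodes(g, traces, set())
        assert len(found) == 1
        assert found[0].covered == (frozenset({"BET"}), frozenset({"CLO", "DEG"}))

    def test_uncovered_backbone_blocks_supernode(self):
        g = SignedNetwork([("x", "y", 0.5)])
        traces = [trace("BET"), trace("CLO", "x", "y"), trace("DEG")]
        assert find_supernodes(g, traces, set()) == []

    def test_disconnected_candidates_rejected(self):
        g = SignedNetwork([("x", "q", 0.5), ("y", "q", 0.5)], nodes=["z"])
        traces = [trace("BET", "x"), trace("CLO", "y"), trace("DEG", "z")]
        assert find_supernodes(g, traces, set()) == []

    def test_agreement_nodes_are_excluded(self):
        g = SignedNetwork([("x", "y", 0.5)])
        traces = [trace("BET", "x", "y"), trace("CLO", "y", "x"), trace("DEG", "x", "y")]
        assert find_supernodes(g, traces, {"x", "y"}) == []


class TestMergeRules:
    """The worked merge rules, symbolic node names."""

    def test_central_triad_rule(self):
        triad = sn((["B1"], ["BET"]), (["C1"], ["CLO"]), (["D1"], ["DEG"]))
        adjacency = sn((["B1"], ["BET"]), (["CD1"], ["CLO", "DEG"]))
        merged = merge_supernodes([triad, adjacency])
        assert len(merged) == 1
        assert merged[0].positions == (
            frozenset({"B1"}),
            frozenset({"C1", "CD1"}),
            frozenset({"D1", "CD1"}),
        )

    def test_upper_triad_double_merge(self):
        triad = sn((["B3"], ["BET"]), (["C5"], ["CLO"]), (["D2"], ["DEG"]))
        a1 = sn((["B3"], ["BET"]), (["CD3"], ["CLO", "DEG"]))
        a2 = sn((["B3"], ["BET"]), (["CD4"], ["CLO", "DEG"]))
        merged = merge_supernodes([triad, a1, a2])
        assert len(merged) == 1
        assert merged[0].positions == (
            frozenset({"B3"}),
            frozenset({"C5", "CD3", "CD4"}),
            frozenset({"D2", "CD3", "CD4"}),
        )

    def test_new_triad_chains_onto_merged_supernode(self):
        triad = sn((["B3"], ["BET"]), (["C5"], ["CLO"]), (["D2"], ["DEG"]))
        a1 = sn((["B3"], ["BET"]), (["CD3"], ["CLO", "DEG"]))
        a2 = sn((["B3"], ["BET"]), (["CD4"], ["CLO", "DEG"]))
        a3 = sn((["B4"], ["BET"]), (["CD3"], ["CLO", "DEG"]))
        merged = merge_supernodes([triad, a1, a2, a3])
        assert len(merged) == 1
        assert merged[0].positions == (
            frozenset({"B3", "B4"}),
            frozenset({"C5", "CD3", "CD4"}),
            frozenset({"D2", "CD3", "CD4"}),
        )

    def test_triads_sharing_two_nodes(self):
        t1 = sn((["x"], ["BET"]), (["y"], ["CLO"]), (["w"], ["DEG"]))
        t2 = sn((["x"], ["BET"]), (["y"], ["CLO"]), (["z"], ["DEG"]))
        merged = merge_supernodes([t1, t2])
        assert len(merged) == 1
        assert merged[0].positions == (
            frozenset({"x"}), frozenset({"y"}), frozenset({"w", "z"})
        )

    def test_triads_sharing_one_node(self):
        t1 = sn((["x"], ["BET"]), (["v"], ["CLO"]), (["w"], ["DEG"]))
        t2 = sn((["x"], ["BET"]), (["y"], ["CLO"]), (["z"], ["DEG"]))
        merged = merge_supernodes([t1, t2])
        assert len(merged) == 1
        assert merged[0].positions == (
            frozenset({"x"}), frozenset({"v", "y"}), frozenset({"w", "z"})
        )

    def test_adjacencies_sharing_one_node(self):
        a1 = sn((["x"], ["BET"]), (["y"], ["CLO", "DEG"]))
        a2 = sn((["x"], ["BET"]), (["z"], ["CLO", "DEG"]))
        merged = merge_supernodes([a1, a2])
        assert len(merged) == 1
        assert merged[0].positions == (frozenset({"x"}), frozenset({"y", "z"}))

    def test_disjoint_supernodes_untouched(self):
        t1 = sn((["a"], ["BET"]), (["b"], ["CLO", "DEG"]))
        t2 = sn((["c"], ["BET"]), (["d"], ["CLO", "DEG"]))
        assert merge_supernodes([t1, t2]) == sorted([t1, t2], key=Supernode.sort_key)

    def test_non_nesting_partitions_flagged_not_merged(self):
        """At k = 4, two supernodes can share a node while their backbone
        partitions do not refine each other; that merge is undefined."""
        s1 = sn((["x"], ["A", "B"]), (["y"], ["C", "D"]))
        s2 = sn((["x"], ["A", "C"]), (["z"], ["B", "D"]))
        report = []
        merged = merge_supernodes([s1, s2], unmerged_report=report)
        assert len(merged) == 2
        assert len(report) == 1


class TestRanking:
    def test_agreement_node_mean_rank(self):
        traces = [
            trace("BET", "a", "q"), trace("CLO", "q", "a"), trace("DEG", "z", "x", "a"),
        ]
        r = rank_elements(["a"], traces)
        assert r.elements[0].rank_score == pytest.approx(2.0)

    def test_supernode_triad_mean_of_finding_backbones(self):
        traces = [
            trace("BET", "q", "r", "s", "x"),
            trace("CLO", "p", "y"),
            trace("DEG", "t", "u", "z"),
        ]
        triad = sn((["x"], ["BET"]), (["y"], ["CLO"]), (["z"], ["DEG"]))
        r = rank_elements([triad], traces)
        assert r.elements[0].rank_score == pytest.approx(3.0)  # (4 + 2 + 3) / 3

    def test_merged_position_uses_earliest_discovery(self):
        traces = [
            trace("BET", "x"),
            trace("CLO", "y", "c2", "c3", "c4", "w"),
            trace("DEG", "y", "w"),
        ]
        merged = sn((["x"], ["BET"]), (["w", "y"], ["CLO", "DEG"]))
        r = rank_elements([merged], traces)
        # CLO: min(rank w=5, rank y=1) = 1; DEG: min(2, 1) = 1; positions (1, 1)
        assert r.elements[0].rank_score == pytest.approx(1.0)

    def test_node_missing_from_a_trace_rejected(self):
        traces = [trace("BET", "a"), trace("CLO", "b")]
        with pytest.raises(KeyError):
            rank_elements(["a"], traces)

    def test_tie_breaks_on_lexicographic_member(self):
        traces = [trace("BET", "b", "a"), trace("CLO", "a", "b")]
        r = rank_elements(["a", "b"], traces)
        assert [e.member for e in r.elements] == ["a", "b"]


class TestConsensusRanking:
    def test_edgeless_network_all_unimportant(self):
        g = SignedNetwork(nodes=["a", "b", "c"])
        r = consensus_ranking(g)
        assert r.elements == [] and r.unimportant == {"a", "b", "c"}
        assert r.unresolvable == set()

    def test_consensus_is_identity_on_full_agreement(self):
        # all three backbones discover exactly [b] on a positive 3-path,
        # so the consensus is that trace verbatim
        g = SignedNetwork([("a", "b", 0.9), ("b", "c", 0.9)])
        r = consensus_ranking(g)
        assert [e.member for e in r.elements] == ["b"]
        assert r.supernodes == [] and r.unresolvable == set()
        assert r.unimportant == {"a", "c"}

    def test_planted_triad_tossup(self):
        from unicent import fixture

        fx = fixture("triad_tossup")
        r = consensus_ranking(fx.network, path_method="exact")
        assert len(r.supernodes) == 1
        assert [set(p) for p in r.supernodes[0].positions] == [
            set(p) for p in fx.expected["supernodes"][0]["positions"]
        ]

    def test_single_backbone_rejected(self):
        with pytest.raises(ValueError):
            consensus_ranking(SignedNetwork([("a", "b", 0.5)]), backbones=("DEG",))

    @pytest.mark.parametrize("seed", range(6))
    def test_four_way_partition_is_exact(self, seed):
        g = generate(GeneratorSpec(n_nodes=24, n_modules=4, seed=seed))
        r = consensus_ranking(g)
        classes = [
            r.agreed_important,
            r.supernode_members,
            r.unresolvable,
            r.unimportant,
        ]
        total = sum(len(c) for c in classes)
        assert total == g.n_nodes
        union = set().union(*classes)
        assert union == set(g.nodes)
        # post-merge supernodes are pairwise disjoint and cover each
        # backbone exactly once
        seen = set()
        for s in r.supernodes:
            assert not (s.base_nodes & seen)
            seen |= s.base_nodes
            assert s.backbone_set == set(r.backbones)
            covered = [b for cov in s.covered for b in cov]
            assert len(covered) == len(set(covered))


class TestExpandedVectorAndSpearman:
    def test_uncovered_nodes_share_tied_last_position(self):
        g = SignedNetwork(nodes=["a", "b", "c", "d"])
        traces = [trace("BET", "a", "b"), trace("CLO", "a", "b"), trace("DEG", "a", "b")]
        r = rank_elements(["a", "b"], traces, unimportant={"c", "d"})
        vec = expanded_rank_vector(r, g)
        assert vec == {"a": 1.0, "b": 2.0, "c": 3.0, "d": 3.0}

    def test_trace_expansion(self):
        g = SignedNetwork(nodes=["a", "b", "c"])
        vec = expanded_rank_vector(trace("DEG", "c"), g)
        assert vec == {"c": 1.0, "a": 2.0, "b": 2.0}

    def test_supernode_members_share_their_position(self):
        g = SignedNetwork([("x", "y", 0.5)], nodes=["u"])
        traces = [trace("BET", "x"), trace("CLO", "y"), trace("DEG", "y")]
        supernode = sn((["x"], ["BET"]), (["y"], ["CLO", "DEG"]))
        r = rank_elements([supernode], traces, unimportant={"u"})
        vec = expanded_rank_vector(r, g)
        assert vec["x"] == vec["y"] == 1.0 and vec["u"] == 2.0

    def test_perfect_and_reversed_correlation(self):
        u = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        assert spearman(u, dict(u)) == pytest.approx(1.0)
        rev = {"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}
        assert spearman(u, rev) == pytest.approx(-1.0)

    def test_four_item_swap_closed_form(self):
        u = {k: float(i) for i, k in enumerate("abcd", 1)}
        v = {"a": 1.0, "b": 2.0, "c": 4.0, "d": 3.0}
        assert spearman(u, v) == pytest.approx(0.8)

    def test_mismatched_key_sets_rejected(self):
        with pytest.raises(ValueError):
            spearman({"a": 1.0, "b": 2.0, "c": 3.0}, {"a": 1.0, "b": 2.0, "d": 3.0})
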