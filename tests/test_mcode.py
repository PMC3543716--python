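"""MCODE vertex weighting, expansion, haircut/fluff and the cut-off sweep."""

import math

import networkx as nx
import numpy as np
import pytest

from aclandscape import preprocess
from aclandscape.landscape import intersect_networks, landscape_from_edge_signs
from aclandscape.mcode import (
    MCODEParams,
    apply_cutoff,
    core_numbers,
    jaccard,
    mcode_find_modules,
    mcode_vertex_weights,
    sweep,
)
from aclandscape.pcit import build_network
from aclandscape.pipeline import DEFAULT_ANALYSIS_GROUPS, resolve_analysis_groups
from aclandscape.synthetic import ModuleSpec, SimulationConfig, generate_expression


def clique(prefix, n):
    g = nx.Graph()
    names = [f"{prefix}{i}" for i in range(n)]
    g.add_edges_from(
        (names[i], names[j]) for i in range(n) for j in range(i + 1, n)
    )
    return g, names


def two_cliques_with_bridge(n=6):
    g1, c1 = clique("a", n)
    g2, c2 = clique("b", n)
    g = nx.compose(g1, g2)
    g.add_edge(c1[0], c2[0])
    return g, c1, c2


class TestApplyCutoff:
    def test_none_keeps_all_and_high_cutoff_empties(self):
        land = landscape_from_edge_signs(
            [("a", "b", 0.9), ("c", "d", -0.9)]
        )
        assert apply_cutoff(land, None).number_of_edges() == 2
        assert apply_cutoff(land, 0.95).number_of_edges() == 0

    def test_strict_threshold_counts(self):
        land = landscape_from_edge_signs(
            [("a", "b", 0.71), ("c", "d", 0.86), ("e", "f", -0.96)]
        )
        for cutoff, want in [(0.7, 3), (0.85, 2), (0.95, 1)]:
            assert apply_cutoff(land, cutoff).number_of_edges() == want

    def test_boundary_is_strict(self):
        land = landscape_from_edge_signs([("a", "b", 0.85)])
        assert apply_cutoff(land, 0.85).number_of_edges() == 0


class TestCoreNumbers:
    def test_clique_and_tree(self):
        g, _ = clique("k", 5)
        assert set(core_numbers(g).values()) == {4}
        t = nx.random_labeled_tree(12, seed=0)
        assert set(core_numbers(t).values()) == {1}

    def test_matches_repeated_deletion_oracle(self):
        g = nx.gnp_random_graph(50, 0.12, seed=3)
        got = core_numbers(g)

        def oracle(graph):
            out = {}
            k = 0
            remaining = graph.copy()
            while remaining.number_of_nodes():
                while True:
                    low = [v for v in remaining if remaining.degree(v) <= k]
                    if not low:
                        break
                    for v in low:
                        out[v] = k
                        remaining.remove_node(v)
                k += 1
            return out

        assert got == oracle(g)


class TestVertexWeights:
    @pytest.mark.parametrize("n", [4, 6, 9])
    def test_clique_vertex_weight_is_n_minus_1(self, n):
        g, names = clique("k", n)
        w = mcode_vertex_weights(g)
        assert all(w[v] == pytest.approx(n - 1) for v in names)

    def test_isolated_vertex_zero(self):
        g = nx.Graph()
        g.add_node("solo")
        assert mcode_vertex_weights(g)["solo"] == 0.0

    def test_star_center_weight_one_third(self):
        g = nx.star_graph(5)
        assert mcode_vertex_weights(g)[0] == pytest.approx(1 / 3)


class TestFindModules:
    def test_two_bridged_cliques_recovered_exactly(self):
        g, c1, c2 = two_cliques_with_bridge(6)
        mods = mcode_find_modules(g, MCODEParams(vwp=0.2))
        assert len(mods) == 2
        assert {frozenset(c1), frozenset(c2)} == {m.genes for m in mods}

    def test_recovery_independent_of_label_order(self):
        g, c1, c2 = two_cliques_with_bridge(6)
        relabel = {c1[0]: "_x", c2[0]: "_y"}  # bridge ends sort first
        g2 = nx.relabel_nodes(g, relabel)
        mods = mcode_find_modules(g2, MCODEParams(vwp=0.2))
        want = {
            frozenset(["_x", *c1[1:]]),
            frozenset(["_y", *c2[1:]]),
        }
        assert {m.genes for m in mods} == want

    def test_edgeless_graph_no_modules(self):
        assert mcode_find_modules(nx.empty_graph(7)) == []

    def test_haircut_removes_pendant_from_k4(self):
        g, names = clique("k", 4)
        g.add_edge(names[0], "pendant")
        mods = mcode_find_modules(g, MCODEParams(vwp=0.2, haircut=True))
        assert len(mods) == 1
        assert mods[0].genes == frozenset(names)

    def test_score_invariant_under_relabelling(self):
        g, c1, c2 = two_cliques_with_bridge(5)
        mods = mcode_find_modules(g)
        g2 = nx.relabel_nodes(g, {v: f"z{v}" for v in g.nodes})
        mods2 = mcode_find_modules(g2)
        assert sorted(m.score for m in mods) == pytest.approx(
            sorted(m.score for m in mods2)
        )

    def test_modules_vertex_disjoint_and_deterministic(self):
        g = nx.gnp_random_graph(40, 0.2, seed=9)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        m1 = mcode_find_modules(g)
        m2 = mcode_find_modules(g)
        assert [m.genes for m in m1] == [m.genes for m in m2]
        seen = set()
        for m in m1:
            assert seen.isdisjoint(m.genes)
            seen |= m.genes


class TestSweep:
    def planted_landscape(self):
        """Edges whose |r| trajectory makes a module grow, then get flooded.

        A K8 core at r=0.9 with two pendant boundary edges; a 4-gene halo
        completing a K12 at r=0.8; 12 outside genes attaching two boundary
        edges each at r=0.72.
        """
        edges = []
        core = [f"m{i}" for i in range(8)]
        halo = [f"h{i}" for i in range(4)]
        dense = core + halo
        for i in range(12):
            for j in range(i + 1, 12):
                r = 0.9 if i < 8 and j < 8 else 0.8
                edges.append((dense[i], dense[j], r))
        edges += [("x1", "m0", 0.9), ("x2", "m0", 0.9)]
        for i in range(12):
            edges.append((f"o{i:02d}", "m0", 0.72))
            edges.append((f"o{i:02d}", "m1", 0.72))
        return landscape_from_edge_signs(edges)

    def test_stable_module_chooses_smallest_cutoff(self):
        edges = [(f"m{i}", f"m{j}", 0.99) for i in range(6) for j in range(i + 1, 6)]
        land = landscape_from_edge_signs(edges)
        res = sweep(land, [0.95, 0.9, 0.8, None], MCODEParams())
        assert len(res.lineages) == 1
        lin = res.lineages[0]
        assert set(lin.history) == {0.95, 0.9, 0.8, None}
        assert lin.chosen_cutoff is None  # the most relaxed grid point

    def test_connectivity_jump_freezes_choice_before_flood(self):
        land = self.planted_landscape()
        res = sweep(land, [0.85, 0.75, 0.7], MCODEParams(), jump_factor=2.0)
        main = max(res.lineages, key=lambda l: max(m.size for m in l.history.values()))
        # at 0.75 the halo joins (bigger module, low boundary); at 0.7 the
        # surrounding 'o' genes triple the boundary -> choice stays at 0.75
        assert main.chosen_cutoff == 0.75
        assert main.chosen_module.size == 12

    def test_low_jaccard_starts_new_lineage(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard({"a", "b", "c"}, {"x", "y"}) == 0.0
        e1 = [(f"p{i}", f"p{j}", 0.9) for i in range(5) for j in range(i + 1, 5)]
        e2 = [(f"q{i}", f"q{j}", 0.6) for i in range(5) for j in range(i + 1, 5)]
        land = landscape_from_edge_signs(e1 + e2)
        res = sweep(land, [0.85, 0.5], MCODEParams())
        # p-clique exists at both cutoffs (one lineage); q-clique appears
        # only at 0.5 as a fresh lineage
        assert len(res.lineages) == 2
        sizes = {lin.lineage_id: set(lin.history) for lin in res.lineages}
        assert sizes[0] == {0.85, 0.5}
        assert sizes[1] == {0.5}

    def test_unsorted_cutoffs_rejected(self):
        land = landscape_from_edge_signs([("a", "b", 0.9)])
        with pytest.raises(ValueError):
            sweep(land, [0.7, 0.9], MCODEParams())


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_top_two_modules_match_planted_truth(self, seed):
        cfg = SimulationConfig(
            seed=seed,
            modules=(
                ModuleSpec(size=30, loading=1.0, negative_fraction=0.3),
                ModuleSpec(size=15, loading=1.0),
            ),
        )
        expr, truth = generate_expression(cfg)
        groups = resolve_analysis_groups(expr, DEFAULT_ANALYSIS_GROUPS)
        nets = [
            build_network(preprocess.preprocess_group(expr, g), g) for g in groups
        ]
        land = intersect_networks(nets, "Overall")
        res = sweep(land, [0.95, 0.9, 0.85, 0.8, 0.7, None], MCODEParams())
        chosen = sorted(
            (lin.chosen_module for lin in res.lineages if lin.chosen_module),
            key=lambda m: -m.size,
        )[:2]
        for mid, planted in [(0, truth.module_genes(0)), (1, truth.module_genes(1))]:
            best = max(jaccard(set(m.genes), planted) for m in chosen)
            assert best >= 0.8, f"module {mid} best Jaccard {best}"
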