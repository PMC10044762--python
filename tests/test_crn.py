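import itertools

import numpy as np
import pandas as pd
import pytest

from phenonet import (
    WEIGHT_GRID,
    InfluenceParams,
    Motif,
    build_crn,
    enumerate_motifs,
    influence_matrix,
    motif_table,
    normalize_features,
    overlay,
    pareto_select,
    score_motif,
)
from phenonet.simulate import SimConfig, make_deg_table, make_map

from conftest import build_map, deg_frame, random_signed_digraph


def oracle_three_cycles(graph):
    """Brute-force directed 3-cycle enumeration over node triples."""
    found = set()
    for triple in itertools.permutations(graph.nodes, 3):
        a, b, c = triple
        if (graph.has_edge(a, b) and graph.has_edge(b, c)
                and graph.has_edge(c, a)):
            found.add(frozenset({(a, b), (b, c), (c, a)}))
    return found


def make_motif(f_i, f_es, f_fc, name="m"):
    nodes = (f"{name}1", f"{name}2", f"{name}3")
    edges = frozenset({(nodes[0], nodes[1], 1), (nodes[1], nodes[2], 1),
                       (nodes[2], nodes[0], 1)})
    return Motif(nodes, edges, f_i, f_es, f_fc)


class TestEnumerate:
    def test_single_triangle(self):
        mim = build_map([("a", "b", 1), ("b", "c", 1), ("c", "a", 1),
                         ("a", "p", 1)], phenotypes=("p",))
        motifs = enumerate_motifs(mim, "p", influence_matrix(mim))
        assert len(motifs) == 1
        assert motifs[0].nodes == ("a", "b", "c")

    def test_both_orientations_are_distinct_motifs(self):
        mim = build_map([("a", "b", 1), ("b", "c", 1), ("c", "a", 1),
                         ("b", "a", 1), ("c", "b", 1), ("a", "c", 1),
                         ("a", "p", 1)], phenotypes=("p",))
        motifs = enumerate_motifs(mim, "p", influence_matrix(mim))
        assert len(motifs) == 2
        assert motifs[0].edges != motifs[1].edges

    def test_acyclic_graph_has_no_motifs(self):
        mim = build_map([("a", "b", 1), ("b", "c", 1), ("a", "p", 1)],
                        phenotypes=("p",))
        assert enumerate_motifs(mim, "p", influence_matrix(mim)) == []

    def test_self_loops_excluded(self):
        mim = build_map([("a", "a", 1), ("a", "b", 1), ("b", "a", 1),
                         ("a", "p", 1)], phenotypes=("p",))
        assert enumerate_motifs(mim, "p", influence_matrix(mim)) == []

    def test_matches_bruteforce_on_random_graphs(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mim, genes, phenos = random_signed_digraph(
                rng, n_nodes=7, p_edge=0.4)
            infl = influence_matrix(mim)
            motifs = enumerate_motifs(mim, phenos[0], infl)
            universe_graph = mim.graph.subgraph(
                set(infl.I.index) & mim.genes)
            expected = oracle_three_cycles(universe_graph)
            got = {frozenset((u, v) for u, v, _ in m.edges) for m in motifs}
            assert got == expected

    def test_candidate_cap_keeps_highest_influence(self):
        mim = build_map(
            [("a", "b", 1), ("b", "c", 1), ("c", "a", 1),
             ("x", "y", 1), ("y", "z", 1), ("z", "x", 1),
             ("a", "p", 1), ("b", "p", 1), ("x", "p", -1)],
            phenotypes=("p",))
        motifs = enumerate_motifs(mim, "p", influence_matrix(mim),
                                  max_candidates=1)
        assert len(motifs) == 1
        assert motifs[0].nodes == ("a", "b", "c")


class TestNormalize:
    def test_min_max_scaling(self):
        motifs = [make_motif(0, 0, 0, "a"), make_motif(5, 5, 5, "b"),
                  make_motif(10, 10, 10, "c")]
        normed = normalize_features(motifs)
        assert normed[0].norm == (0.0, 0.0, 0.0)
        assert normed[1].norm == (0.5, 0.5, 0.5)
        assert normed[2].norm == (1.0, 1.0, 1.0)

    def test_single_motif_gets_half_by_convention(self):
        normed = normalize_features([make_motif(7, 0, 3)])
        assert normed[0].norm == (0.5, 0.5, 0.5)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            normalize_features([])

    def test_random_population_bounded_and_order_preserving(self, rng):
        motifs = [make_motif(*rng.normal(size=3), name=f"m{i}")
                  for i in range(30)]
        normed = normalize_features(motifs)
        arr = np.array([m.norm for m in normed])
        assert ((arr >= 0) & (arr <= 1)).all()
        for k, attr in enumerate(
                ["f_influence", "f_enrichment", "f_foldchange"]):
            raw = np.array([getattr(m, attr) for m in motifs])
            for i in range(len(motifs)):
                for j in range(len(motifs)):
                    if raw[i] < raw[j]:
                        assert arr[i, k] <= arr[j, k]


class TestScore:
    @pytest.mark.parametrize("norm,weights,expected", [
        ((1.0, 1.0, 1.0), (1.0, 1.0, 1.0), 3.0),
        ((1.0, 0.0, 0.0), (0.33, 0.66, 1.0), 0.33),
        ((0.5, 0.4, 0.9), (0.66, 0.33, 1.0), 1.362),
    ])
    def test_worked_examples(self, norm, weights, expected):
        motif = make_motif(0, 0, 0)
        motif = Motif(motif.nodes, motif.edges, 0, 0, 0, norm=norm)
        assert score_motif(motif, weights) == pytest.approx(expected)

    def test_unnormalized_motif_rejected(self):
        with pytest.raises(ValueError):
            score_motif(make_motif(1, 1, 1), (1.0, 1.0, 1.0))

    def test_linearity_per_scenario(self, rng):
        a = rng.uniform(size=3)
        b = rng.uniform(size=3)
        mean = (a + b) / 2
        motifs = [
            Motif(m.nodes, m.edges, 0, 0, 0, norm=tuple(v))
            for m, v in zip(
                [make_motif(0, 0, 0, n) for n in "abc"], [a, b, mean])
        ]
        for scenario in WEIGHT_GRID:
            sa, sb, sm = (score_motif(m, scenario) for m in motifs)
            assert sm == pytest.approx((sa + sb) / 2)


class TestParetoSelect:
    def test_weight_grid_has_27_scenarios(self):
        assert len(WEIGHT_GRID) == 27
        assert len(set(WEIGHT_GRID)) == 27

    def test_dominating_motif_selected_alone(self):
        motifs = normalize_features(
            [make_motif(10, 10, 10, "top")]
            + [make_motif(1, 1, 1, f"m{i}") for i in range(5)])
        selected = pareto_select(motifs, top_m=1)
        assert len(selected) == 1
        assert selected[0].nodes == ("top1", "top2", "top3")

    def test_feature_specialists_both_selected(self):
        # one motif best on F_I, another best on F_FC: each wins some
        # scenario, so both join the union at top_m = 1
        motifs = normalize_features(
            [make_motif(1, 0, 0, "a"), make_motif(0, 0, 1, "b"),
             make_motif(0.1, 0.1, 0.1, "c")])
        selected = pareto_select(motifs, top_m=1)
        names = {m.nodes[0][0] for m in selected}
        assert {"a", "b"} <= names

    def test_fewer_motifs_than_top_m_selects_all(self):
        motifs = normalize_features([make_motif(1, 2, 3)])
        assert len(pareto_select(motifs, top_m=5)) == 1

    @pytest.mark.parametrize("top_m", [1, 2, 3])
    def test_dominance_implies_coselection(self, top_m):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            motifs = normalize_features(
                [make_motif(*rng.uniform(size=3), name=f"m{i:02d}")
                 for i in range(15)])
            selected = {m.key for m in pareto_select(motifs, top_m=top_m)}
            arr = {m.key: np.array(m.norm) for m in motifs}
            for m_b in motifs:
                if m_b.key not in selected:
                    continue
                for m_a in motifs:
                    if m_a.key == m_b.key:
                        continue
                    if ((arr[m_a.key] >= arr[m_b.key]).all()
                            and (arr[m_a.key] > arr[m_b.key]).any()):
                        assert m_a.key in selected

    def test_deterministic_tie_break(self):
        motifs = normalize_features(
            [make_motif(1, 1, 1, "b"), make_motif(1, 1, 1, "a"),
             make_motif(0, 0, 0, "z")])
        selected = pareto_select(motifs, top_m=1)
        assert selected[0].nodes == ("a1", "a2", "a3")


class TestBuildCRN:
    def test_two_motifs_sharing_a_node_merge(self):
        m1 = make_motif(1, 1, 1, "a")
        shared = ("a1", "x2", "x3")
        m2 = Motif(shared, frozenset({
            ("a1", "x2", 1), ("x2", "x3", -1), ("x3", "a1", 1)}), 1, 1, 1)
        crn = build_crn([m1, m2], "p")
        assert crn.graph.number_of_nodes() == 5
        assert crn.graph.number_of_edges() == 6

    def test_annotation_matches_overlay_signs(self):
        mim = build_map([("a", "b", 1), ("b", "c", 1), ("c", "a", 1),
                         ("a", "p", 1)], phenotypes=("p",))
        infl = influence_matrix(mim)
        ov = overlay(mim, deg_frame(
            [(12, "a", 2.0, 0.01), (12, "b", -1.0, 0.01),
             (12, "c", 1.0, 0.9)]), "A")[12]
        motifs = normalize_features(enumerate_motifs(mim, "p", infl))
        crn = build_crn(pareto_select(motifs), "p", ov)
        assert crn.graph.nodes["a"]["regulation"] == "up"
        assert crn.graph.nodes["b"]["regulation"] == "down"
        assert crn.graph.nodes["c"]["regulation"] == "none"

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="relax"):
            build_crn([], "p")

    def test_graphml_export(self, tmp_path):
        crn = build_crn([make_motif(1, 1, 1)], "p")
        crn.to_graphml(tmp_path / "crn.graphml")
        assert (tmp_path / "crn.graphml").stat().st_size > 0


def test_planted_motif_appears_in_generated_crn():
    """On the synthetic planted network (seed 7), the planted
    high-feature feedback loop must survive Pareto selection into the CRN."""
    cfg = SimConfig(seed=7)
    mim, truth = make_map(cfg)
    infl = influence_matrix(mim)
    deg = make_deg_table(cfg, truth.planted_fc, sorted(mim.genes))
    ov = overlay(mim, deg, "treatment_vs_control")[120]
    motifs = enumerate_motifs(mim, truth.target_phenotype, infl,
                              fc=ov.table["log2fc"])
    motifs = normalize_features(motifs)
    selected = pareto_select(motifs, top_m=5)
    crn = build_crn(selected, truth.target_phenotype, ov)
    planted = truth.planted_motifs[0]
    assert planted in [m.nodes for m in selected]
    assert set(planted) <= set(crn.graph.nodes)
    table = motif_table(selected)
    assert ";".join(planted) in set(table["nodes"])
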