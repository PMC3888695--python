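import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import complexwalk as cw
from complexwalk.layers import (
    assign_tissue,
    build_disease_layer_knn,
    build_disease_layer_threshold,
    build_disease_protein_links,
    build_protein_complex_links,
    build_tissue_ppi_erw,
    build_tissue_ppi_nr,
    graph_from_edge_table,
)
from complexwalk.io import edge_table_from_pairs


def _random_profile(rng, l):
    vals = rng.random((l, l))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    return cw.SimilarityProfile([f"d{i:03d}" for i in range(l)], vals)


class TestDiseaseLayerKnn:
    def test_k1_union_edges(self, tiny_profile):
        g = build_disease_layer_knn(tiny_profile, k=1)
        assert g.edge_set() == {("da", "db"), ("db", "dc")}
        assert g.adjacency[g.index("da"), g.index("db")] == 0.9
        assert g.adjacency[g.index("db"), g.index("dc")] == 0.5

    def test_k_saturation_gives_complete_graph(self, tiny_profile):
        g = build_disease_layer_knn(tiny_profile, k=2)
        assert g.n_edges == 3

    def test_unweighted_variant_has_unit_weights(self, tiny_profile):
        g = build_disease_layer_knn(tiny_profile, k=1, weighted=False)
        assert g.edge_set() == {("da", "db"), ("db", "dc")}
        assert set(g.adjacency.data) == {1.0}

    def test_mutual_mode_is_subset_of_union(self, tiny_profile):
        union = build_disease_layer_knn(tiny_profile, k=1, mode="union")
        mutual = build_disease_layer_knn(tiny_profile, k=1, mode="mutual")
        assert mutual.edge_set() <= union.edge_set()
        # da and db pick each other; dc's pick of db is one-sided
        assert mutual.edge_set() == {("da", "db")}

    @given(st.integers(0, 1000), st.integers(1, 6))
    @settings(max_examples=25, deadline=None)
    def test_union_edge_count_bounds(self, seed, k):
        rng = np.random.default_rng(seed)
        l = int(rng.integers(k + 2, 16))
        g = build_disease_layer_knn(_random_profile(rng, l), k=k)
        assert np.ceil(l * k / 2) <= g.n_edges <= l * k
        degrees = np.diff(g.adjacency.indptr)
        assert (degrees >= k).all()


class TestDiseaseLayerThreshold:
    def test_threshold_membership(self, tiny_profile):
        g = build_disease_layer_threshold(tiny_profile, delta=0.35)
        assert g.edge_set() == {("da", "db"), ("db", "dc")}

    def test_delta_zero_complete_delta_high_empty(self, tiny_profile):
        assert build_disease_layer_threshold(tiny_profile, 0.0).n_edges == 3
        assert build_disease_layer_threshold(tiny_profile, 0.95).n_edges == 0

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_edge_set_monotone_nonincreasing_in_delta(self, seed):
        rng = np.random.default_rng(seed)
        prof = _random_profile(rng, 8)
        deltas = sorted(rng.random(4))
        sets = [
            build_disease_layer_threshold(prof, d).edge_set() for d in deltas
        ]
        for a, b in zip(sets, sets[1:]):
            assert b <= a


class TestAssignTissue:
    def test_argmax(self):
        scores = cw.DiseaseTissueScores(
            ["d1"], ["brain", "liver"], np.array([[0.8, 0.3]])
        )
        assert assign_tissue("d1", scores) == "brain"

    def test_tie_breaks_by_file_order(self):
        scores = cw.DiseaseTissueScores(
            ["d1"], ["brain", "liver"], np.array([[0.5, 0.5]])
        )
        assert assign_tissue("d1", scores) == "brain"

    def test_unknown_disease_raises(self):
        scores = cw.DiseaseTissueScores(["d1"], ["brain"], np.array([[0.5]]))
        with pytest.raises(cw.DiseaseLookupError):
            assign_tissue("dX", scores)


@pytest.fixture
def chain_graph():
    table = edge_table_from_pairs([("p1", "p2"), ("p2", "p3")])
    return graph_from_edge_table(table)


class TestTissuePpi:
    def test_node_removal_drops_incident_edges(self, chain_graph):
        g = build_tissue_ppi_nr(chain_graph, {"p1", "p2"})
        assert g.edge_set() == {("p1", "p2")}
        assert g.node_ids == chain_graph.node_ids  # p3 kept, isolated

    def test_node_removal_identity_when_all_expressed(self, chain_graph):
        g = build_tissue_ppi_nr(chain_graph, {"p1", "p2", "p3"})
        assert (g.adjacency != chain_graph.adjacency).nnz == 0

    def test_node_removal_empty_expression(self, chain_graph):
        assert build_tissue_ppi_nr(chain_graph, set()).n_edges == 0

    @pytest.mark.parametrize(
        "expressed, expected",
        [
            ({"p1", "p2"}, 1.0),
            ({"p1"}, 0.1),
            (set(), 0.01),
        ],
    )
    def test_erw_penalty_per_nonexpressed_endpoint(self, expressed, expected):
        table = edge_table_from_pairs([("p1", "p2")])
        g = build_tissue_ppi_erw(graph_from_edge_table(table), expressed, rw=0.1)
        assert g.adjacency[g.index("p1"), g.index("p2")] == pytest.approx(expected)

    def test_erw_rw1_equals_generic_rw0_matches_nr_support(self):
        rng = np.random.default_rng(11)
        pairs = [
            (f"p{i}", f"p{j}")
            for i in range(10)
            for j in range(i + 1, 10)
            if rng.random() < 0.3
        ]
        g = graph_from_edge_table(edge_table_from_pairs(pairs))
        expressed = {p for p in g.node_ids if rng.random() < 0.5}
        same = build_tissue_ppi_erw(g, expressed, rw=1.0)
        assert (same.adjacency != g.adjacency).nnz == 0
        erw0 = build_tissue_ppi_erw(g, expressed, rw=0.0)
        nr = build_tissue_ppi_nr(g, expressed)
        assert erw0.edge_set() == nr.edge_set()

    def test_rw_out_of_range_rejected(self, chain_graph):
        with pytest.raises(cw.ParameterError):
            build_tissue_ppi_erw(chain_graph, set(), rw=1.5)


class TestBipartiteLinks:
    def test_alpha_weights_and_positivity(self):
        pairs = edge_table_from_pairs([("d1", "p1"), ("d2", "p2")])
        links = build_disease_protein_links(pairs, alpha=1000.0)
        assert links.uniform_weight == 1000.0
        assert len(links.pairs) == 2
        with pytest.raises(cw.ParameterError):
            build_disease_protein_links(pairs, alpha=0.0)

    def test_beta_weights_and_member_drop(self, caplog):
        import logging

        membership = edge_table_from_pairs(
            [("c1", "p1"), ("c1", "p2"), ("c2", "px")]
        )
        with caplog.at_level(logging.WARNING):
            links = build_protein_complex_links(
                membership, beta=10.0, protein_ids=["p1", "p2"]
            )
        assert links.right_ids == ["c1"]
        assert links.pairs == {("p1", "c1"), ("p2", "c1")}
        assert links.uniform_weight == 10.0
        assert any("no member" in r.message for r in caplog.records)
        with pytest.raises(cw.ParameterError):
            build_protein_complex_links(membership, beta=-1.0)


class TestLayerInvariants:
    @given(st.integers(0, 500))
    @settings(max_examples=15, deadline=None)
    def test_all_layers_symmetric_zero_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        prof = _random_profile(rng, 9)
        for g in (
            build_disease_layer_knn(prof, k=2),
            build_disease_layer_threshold(prof, 0.4),
        ):
            assert abs(g.adjacency - g.adjacency.T).nnz == 0
            assert not g.adjacency.diagonal().any()
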