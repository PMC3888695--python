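import numpy as np
import pytest

import complexwalk as cw
from complexwalk.network import normalize
from complexwalk.walk import RestartVector, solve_walk_direct


class TestWorkedExample:
    def test_directly_annotated_complex_ranks_first(self, worked_bundle):
        res = cw.DiseaseComplexModel(worked_bundle).fit("d1")
        assert res.ranking["complex_id"].iloc[0] == "c1"
        assert res.rank_of("c1") == 1.0

    def test_walk_matches_dense_linear_solve(self, worked_bundle):
        model = cw.DiseaseComplexModel(worked_bundle)
        net = model.build_network("d1")
        tm = normalize(net)
        q0 = RestartVector.for_query(net.n_nodes, net.node_index("d1"))
        res = model.fit("d1")
        direct = solve_walk_direct(tm, q0, gamma=model.gamma)
        assert np.max(np.abs(res.q_inf - direct)) <= 10 * model.epsilon

    def test_scores_match_brute_force_pipeline(self, worked_bundle):
        """End-to-end oracle: dense numpy reimplementation of the pipeline."""
        model = cw.DiseaseComplexModel(worked_bundle)
        net = model.build_network("d2")
        H = net.H.toarray()
        rs = H.sum(axis=1, keepdims=True)
        T = np.divide(H, rs, out=np.zeros_like(H), where=rs > 0)
        q0 = np.zeros(net.n_nodes)
        q0[net.node_index("d2")] = 1.0
        direct = model.gamma * np.linalg.solve(
            np.eye(net.n_nodes) - (1 - model.gamma) * T.T, q0
        )
        mass = direct[net.complex_slice()]
        expected = dict(zip(net.complex_ids, mass / mass.sum()))
        res = model.fit("d2")
        for c, s in res.scores.items():
            assert s == pytest.approx(expected[c], abs=1e-4)

    def test_gamma_one_cannot_score_complexes(self, worked_bundle):
        model = cw.DiseaseComplexModel(worked_bundle, gamma=1.0)
        with pytest.raises(cw.ScoringError):
            model.fit("d1")

    def test_empty_disease_layer_still_prioritizes_via_alpha_edges(
        self, worked_bundle
    ):
        model = cw.DiseaseComplexModel(
            worked_bundle, disease_layer="threshold", delta=1.0
        )
        assert model.disease_graph.n_edges == 0
        res = model.fit("d1")
        assert res.ranking["complex_id"].iloc[0] == "c1"

    def test_unknown_query_raises_lookup_error(self, worked_bundle):
        with pytest.raises(cw.DiseaseLookupError):
            cw.DiseaseComplexModel(worked_bundle).fit("dX")


class TestNeighbourBorrowing:
    def test_query_without_annotations_borrows_from_neighbour(
        self, worked_bundle
    ):
        """A disease with no direct protein edges still recovers the
        complexes of its phenotype neighbour (information borrowing)."""
        model = cw.DiseaseComplexModel(worked_bundle)
        # mask d1's own associations: only its similar neighbour d2 (-> p2
        # in c1) can route mass to complexes
        res = model.fit("d1", mask_query_associations=True)
        assert res.ranking["complex_id"].iloc[0] == "c1"
        # brute-force check of the same masked network
        net = model.build_network("d1", mask_query_associations=True)
        H = net.H.toarray()
        rs = H.sum(axis=1, keepdims=True)
        T = np.divide(H, rs, out=np.zeros_like(H), where=rs > 0)
        q0 = np.zeros(net.n_nodes)
        q0[net.node_index("d1")] = 1.0
        direct = model.gamma * np.linalg.solve(
            np.eye(net.n_nodes) - (1 - model.gamma) * T.T, q0
        )
        mass = direct[net.complex_slice()]
        assert net.complex_ids[int(np.argmax(mass))] == "c1"


class TestTissueSelection:
    def test_auto_tissue_follows_highest_score(self, worked_bundle):
        model = cw.DiseaseComplexModel(worked_bundle)
        assert model.tissue_for("d1") == "t1"
        assert model.tissue_for("d3") == "t2"

    def test_explicit_override_wins(self, worked_bundle):
        model = cw.DiseaseComplexModel(worked_bundle, tissue="t2")
        assert model.tissue_for("d1") == "t2"

    def test_generic_strategy_ignores_tissue(self, worked_bundle):
        model = cw.DiseaseComplexModel(worked_bundle, ppi="generic")
        assert model.tissue_for("d1") is None

    def test_nr_and_erw_strategies_run(self, worked_bundle):
        for strategy in ("nr", "erw", "generic"):
            res = cw.DiseaseComplexModel(worked_bundle, ppi=strategy).fit("d1")
            assert res.n_candidates == 3


class TestNaiveBaseline:
    def test_shared_protein_double_counted(self, worked_bundle):
        """The naive score of a complex is the raw sum over members, so a
        protein shared between complexes contributes to each."""
        model = cw.DiseaseComplexModel(worked_bundle)
        res = model.fit("d1", method="naive")
        # recompute from the protein masses of the same two-layer walk
        net = model.build_network("d1", include_complex_layer=False)
        members = model.complex_members
        protein_mass = {
            p: float(res.q_inf[net.node_index(p)]) for p in net.protein_ids
        }
        for c, ps in members.items():
            assert res.scores[c] == pytest.approx(
                sum(protein_mass[p] for p in ps), abs=1e-12
            )


class TestResultsSurface:
    def test_summary_mentions_query_and_top_candidate(self, worked_bundle):
        res = cw.DiseaseComplexModel(worked_bundle).fit("d1")
        text = res.summary()
        assert "d1" in text and "c1" in text
        assert "gamma=0.5" in text

    def test_save_round_trip(self, worked_bundle, tmp_path):
        res = cw.DiseaseComplexModel(worked_bundle).fit("d1")
        res.save(tmp_path / "r.tsv")
        query, back = cw.io.read_ranking(tmp_path / "r.tsv")
        assert query == "d1"
        assert list(back["complex_id"]) == list(res.ranking["complex_id"])

    def test_convergence_diagnostics_recorded(self, worked_bundle):
        res = cw.DiseaseComplexModel(worked_bundle).fit("d1")
        assert res.iterations >= 1
        assert res.final_delta <= res.model.epsilon
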