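import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import complexwalk as cw
from complexwalk.evaluation import (
    ValidationRun,
    compare_methods,
    compute_metrics,
    derive_test_cases,
    label_shuffled_loocv,
    loocv_run,
    random_guess_expectation,
    rank_roc,
    shuffle_disease_labels,
)
from complexwalk.io import edge_table_from_pairs


def _runs(ranks, list_length):
    return [
        ValidationRun(
            test_complex_id=f"c{i}",
            query_disease_id=f"d{i}",
            masked_pairs=(),
            rank=float(r),
            list_length=list_length,
        )
        for i, r in enumerate(ranks)
    ]


def _mann_whitney_auc(tests, controls):
    """Independent oracle: normalized U with ties counted half."""
    wins = sum(
        1.0 if t < c else (0.5 if t == c else 0.0)
        for t in tests
        for c in controls
    )
    return wins / (len(tests) * len(controls))


class TestDeriveTestCases:
    def test_annotated_member_defines_association(self):
        dp = edge_table_from_pairs([("d1", "p1")])
        mem = edge_table_from_pairs([("c1", "p1")])
        assert derive_test_cases(dp, mem) == [("c1", "d1")]

    def test_unannotated_complex_excluded(self):
        dp = edge_table_from_pairs([("d1", "p1")])
        mem = edge_table_from_pairs([("c1", "p1"), ("c2", "p2")])
        assert derive_test_cases(dp, mem) == [("c1", "d1")]

    def test_pair_mode_yields_one_run_per_association(self):
        dp = edge_table_from_pairs([("d1", "p1"), ("d2", "p2")])
        mem = edge_table_from_pairs([("c1", "p1"), ("c1", "p2")])
        assert derive_test_cases(dp, mem, one_run_per_complex=False) == [
            ("c1", "d1"),
            ("c1", "d2"),
        ]
        # default mode collapses to the lexicographically smallest disease
        assert derive_test_cases(dp, mem) == [("c1", "d1")]


class TestComputeMetrics:
    def test_direct_arithmetic(self):
        report = compute_metrics(_runs([1, 1, 3], 10))
        assert report.top_counts[1] == 2
        assert report.PRE == pytest.approx(2 / 3)
        assert report.MR == pytest.approx(5 / 3)
        assert report.MRR == pytest.approx(1 / 6)

    def test_mean_rank_normalization_identity(self):
        """MR 169.04 over lists of 1343 candidates is MRR 12.59%."""
        assert round(100 * 169.04 / 1343, 2) == 12.59

    def test_all_worst_ranks(self):
        report = compute_metrics(_runs([10, 10], 10))
        assert report.PRE == 0.0
        assert report.MRR == 1.0

    def test_mrr_equals_mr_over_shared_list_length(self):
        ranks = [3, 7, 1, 9]
        report = compute_metrics(_runs(ranks, 20))
        assert report.MRR == pytest.approx(report.MR / 20)


class TestRankRoc:
    def test_perfect_separation(self):
        _, auc = rank_roc([0.01] * 5, np.linspace(0.2, 0.9, 40))
        assert auc == 1.0

    def test_three_point_brute_force(self):
        _, auc = rank_roc([0.2], [0.1, 0.3])
        assert auc == 0.5

    def test_identical_distributions_approach_half(self):
        rng = np.random.default_rng(2024)
        tests = rng.random(10_000)
        controls = rng.random(10_000)
        _, auc = rank_roc(tests, controls)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_empty_control_list_rejected(self):
        with pytest.raises(cw.ValidationError):
            rank_roc([0.1], [])

    def test_auc_equals_normalized_mann_whitney_exhaustive(self):
        grid = [0.1, 0.3, 0.5, 0.9]
        for nt, nc in [(1, 1), (1, 2), (2, 2), (2, 3)]:
            for tests in itertools.combinations_with_replacement(grid, nt):
                for controls in itertools.combinations_with_replacement(grid, nc):
                    _, auc = rank_roc(tests, controls)
                    assert auc == pytest.approx(
                        _mann_whitney_auc(tests, controls), abs=1e-12
                    )

    @given(
        st.lists(st.sampled_from([i / 8 for i in range(1, 9)]), min_size=1,
                 max_size=8),
        st.lists(st.sampled_from([i / 8 for i in range(1, 9)]), min_size=1,
                 max_size=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_auc_equals_normalized_mann_whitney_property(self, tests, controls):
        _, auc = rank_roc(tests, controls)
        assert auc == pytest.approx(_mann_whitney_auc(tests, controls),
                                    abs=1e-12)

    def test_cross_check_against_scipy_u_statistic(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(5)
        tests = rng.random(30)
        controls = rng.random(50)
        _, auc = rank_roc(tests, controls)
        u = mannwhitneyu(controls, tests, alternative="two-sided").statistic
        assert auc == pytest.approx(u / (30 * 50), abs=1e-12)


class TestRandomGuess:
    @pytest.mark.parametrize(
        "t, expected",
        [(1, 0.70), (5, 3.50), (10, 6.99), (20, 13.98)],
    )
    def test_reference_expectations(self, t, expected):
        count, _ = random_guess_expectation(939, 1343, t)
        assert round(count, 2) == expected

    def test_full_threshold_is_certainty(self):
        count, frac = random_guess_expectation(939, 1343, 1343)
        assert count == 939
        assert frac == 1.0

    def test_top1_count_times_n_equals_runs(self):
        count, _ = random_guess_expectation(250, 500, 1)
        assert count * 500 == 250


class TestCompareMethods:
    def test_identical_runs_identical_rows(self):
        runs = _runs([1, 2, 3], 10)
        for r in runs:
            r.control_relative_ranks = np.array([0.4, 0.8])
        table = compare_methods({"a": runs, "b": list(runs)})
        assert (table.loc["a"] == table.loc["b"]).all()

    def test_uniformly_better_ranks_win_all_criteria(self):
        better = _runs([1, 1, 2], 10)
        worse = _runs([3, 4, 5], 10)
        for b, w in zip(better, worse):
            b.control_relative_ranks = np.array([0.5, 0.9])
            w.control_relative_ranks = np.array([0.5, 0.9])
        table = compare_methods({"better": better, "worse": worse})
        assert table.loc["better", "PRE"] > table.loc["worse", "PRE"]
        assert table.loc["better", "MR"] < table.loc["worse", "MR"]
        assert table.loc["better", "AUC"] > table.loc["worse", "AUC"]

    def test_mismatched_case_sets_rejected(self):
        with pytest.raises(cw.ValidationError):
            compare_methods({"a": _runs([1], 10), "b": _runs([1, 2], 10)})


class TestLoocv:
    def test_disconnected_query_gets_worst_rank_flagged(self, worked_bundle):
        # with an empty disease layer and masked associations, the query
        # cannot reach any complex
        model = cw.DiseaseComplexModel(
            worked_bundle, disease_layer="threshold", delta=1.0
        )
        run = loocv_run(("c1", "d1"), model)
        assert run.flagged
        assert run.rank == run.list_length == 3
        assert run.masked_pairs == (("d1", "p1"),)

    def test_masked_pairs_are_exactly_the_query_associations(
        self, planted_model, planted_runs
    ):
        run = planted_runs[0]
        expected = {
            (a, b)
            for a, b in planted_model.bundle.disease_protein.pairs()
            if a == run.query_disease_id
        }
        assert set(run.masked_pairs) == expected

    def test_planted_signal_beats_shuffled_labels(
        self, planted_model, planted_runs
    ):
        """Planted disease-cluster signal is recovered: mean relative rank
        under the true network is far better than under the permutation
        null on the same test cases."""
        planted = compute_metrics(planted_runs)
        rng = np.random.default_rng(123)
        null = compute_metrics(label_shuffled_loocv(planted_model, rng))
        assert planted.MRR < null.MRR - 0.2
        assert planted.AUC > null.AUC + 0.2

    def test_rwr_and_naive_both_far_above_random(
        self, planted_model, planted_runs
    ):
        cases = [(r.test_complex_id, r.query_disease_id) for r in planted_runs]
        naive_runs = cw.run_loocv(planted_model, cases=cases, method="naive")
        table = compare_methods({"rwr": planted_runs, "naive": naive_runs})
        n = planted_runs[0].list_length
        _, random_pre = random_guess_expectation(len(planted_runs), n, 1)
        assert table.loc["rwr", "AUC"] > 0.7
        assert table.loc["naive", "AUC"] > 0.7
        assert table.loc["rwr", "PRE"] > 3 * random_pre
        assert table.loc["naive", "PRE"] > 3 * random_pre


class TestShuffleLabels:
    def test_preserves_protein_and_disease_universes(self, planted_bundle):
        rng = np.random.default_rng(9)
        shuffled = shuffle_disease_labels(planted_bundle.disease_protein, rng)
        orig = planted_bundle.disease_protein.records
        # the permutation reassigns labels; duplicates that arise collapse,
        # but no protein or disease disappears from the table
        assert set(shuffled.records["node_b"]) == set(orig["node_b"])
        assert set(shuffled.records["node_a"]) == set(orig["node_a"])
        assert shuffled.n_edges <= orig.shape[0]
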