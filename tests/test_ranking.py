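import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reosig import (
    PairedCohort,
    ExpressionMatrix,
    cohort_consistency,
    consistency_score,
    count_gene_pairs,
    exclusion_mask,
    rank_diff,
    rank_sample,
)
from reosig.ranking import NoEvaluablePairsError, ReoError

from _naive import naive_consistency, naive_ranks


class TestRankSample:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([5, 1, 3], [3, 1, 2]),
            ([2, 2, 7], [1.5, 1.5, 3]),
            ([4], [1]),
            ([1, 1, 1, 1], [2.5, 2.5, 2.5, 2.5]),
        ],
    )
    def test_ascending_midranks(self, values, expected):
        np.testing.assert_array_equal(rank_sample(values), expected)

    def test_empty_vector_rejected(self):
        with pytest.raises(ReoError):
            rank_sample([])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=100).map(lambda x: round(x, 1)),
            min_size=1,
            max_size=30,
        )
    )
    def test_matches_sort_based_midrank_oracle(self, values):
        np.testing.assert_allclose(rank_sample(values), naive_ranks(values))


class TestPairCounting:
    @pytest.mark.parametrize("n, expected", [(2, 1), (5, 10), (100, 4950)])
    def test_binomial_coefficient(self, n, expected):
        assert count_gene_pairs(n) == expected

    def test_fewer_than_two_genes_rejected(self):
        with pytest.raises(ReoError):
            count_gene_pairs(1)


class TestRankDiff:
    def test_absolute_difference(self):
        assert rank_diff(np.array([3.0, 1.0, 2.0]), 0, 1) == 2

    def test_tied_midranks_give_zero(self):
        assert rank_diff(rank_sample([2, 2, 7]), 0, 1) == 0

    def test_extremes_span_n_minus_one(self):
        n = 10
        assert rank_diff(np.arange(1.0, n + 1), 0, n - 1) == n - 1

    def test_same_gene_rejected(self):
        with pytest.raises(ReoError):
            rank_diff(np.array([1.0, 2.0]), 1, 1)


class TestExclusionMask:
    def test_fraction_zero_excludes_nothing(self):
        assert exclusion_mask(rank_sample([1, 5, 9]), ["A", "B", "C"], 0.0) == set()

    def test_half_of_three_pairs_excludes_single_closest(self):
        # values 1, 2, 9: closest pair by rank difference is (A, B)
        ranks = rank_sample([1, 2, 9])
        out = exclusion_mask(ranks, ["A", "B", "C"], 0.5)
        assert out == {("A", "B")}

    def test_floor_semantics(self):
        ranks = rank_sample([1, 2, 9])
        assert exclusion_mask(ranks, ["A", "B", "C"], 0.1) == set()

    def test_fraction_one_rejected(self):
        with pytest.raises(ReoError):
            exclusion_mask(rank_sample([1, 2]), ["A", "B"], 1.0)

    def test_lexicographic_tiebreak_at_cut(self):
        # consecutive integers: all adjacent pairs share the minimal rank
        # diff of 1; with 4 genes (6 pairs) and fraction 1/3, exactly 2 of
        # the 3 adjacent pairs are dropped, the lexicographically smallest.
        ranks = rank_sample([10, 20, 30, 40])
        out = exclusion_mask(ranks, ["D", "C", "B", "A"], 2 / 6)
        assert out == {("A", "B"), ("B", "C")}

    @pytest.mark.parametrize("fraction", [0.0, 0.1, 0.25, 0.5, 0.9])
    def test_exact_count_on_random_vectors(self, rng, fraction):
        values = np.round(rng.lognormal(0, 1, 25), 1)  # forces some ties
        ids = [f"G{i:02d}" for i in range(25)]
        out = exclusion_mask(rank_sample(values), ids, fraction)
        assert len(out) == int(np.floor(fraction * count_gene_pairs(25) + 1e-9))


class TestConsistencyScore:
    def test_monotone_transform_scores_one(self):
        rec = consistency_score([1, 2, 3], [2, 4, 6])
        assert rec.score == 1.0 and rec.n_evaluated == 3

    def test_single_swap_scores_two_thirds(self):
        rec = consistency_score([1, 2, 3], [2, 1, 3])
        assert rec.k_consistent == 2 and rec.n_evaluated == 3
        assert rec.score == pytest.approx(2 / 3)

    def test_full_reversal_scores_zero(self):
        assert consistency_score([1, 2, 3], [3, 2, 1]).score == 0.0

    def test_ties_excluded_from_numerator_and_denominator(self):
        rec = consistency_score([1, 1, 3], [5, 2, 9])
        assert rec.n_tied == 1 and rec.n_evaluated == 2

    def test_all_tied_raises(self):
        with pytest.raises(NoEvaluablePairsError):
            consistency_score([2, 2, 2], [1, 2, 3])

    def test_symmetric_without_ties_at_fraction_zero(self, rng):
        a = rng.lognormal(0, 1, 30)
        b = rng.lognormal(0, 1, 30)
        r1 = consistency_score(a, b)
        r2 = consistency_score(b, a)
        assert r1.k_consistent == r2.k_consistent
        assert r1.n_evaluated == r2.n_evaluated

    @pytest.mark.parametrize(
        "transform", [lambda x: 3 * x + 0.5, lambda x: x**2, np.exp]
    )
    def test_invariant_under_strictly_increasing_transforms(self, rng, transform):
        a = rng.lognormal(0, 1, 40)
        b = rng.lognormal(0, 1, 40)
        base = consistency_score(a, b, fraction=0.1)
        warped = consistency_score(transform(a), transform(b), fraction=0.1)
        assert (base.k_consistent, base.n_evaluated, base.n_tied) == (
            warped.k_consistent, warped.n_evaluated, warped.n_tied
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    @pytest.mark.parametrize("fraction", [0.0, 0.1, 0.2, 0.37])
    def test_blocked_kernel_matches_naive_enumeration(self, seed, fraction):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        ff = np.round(rng.lognormal(0, 1, n), 1)
        ffpe = np.round(ff * rng.lognormal(0, 0.5, n), 1)
        ids = [f"G{i:02d}" for i in range(n)]
        rec = consistency_score(ff, ffpe, fraction=fraction, gene_ids=ids)
        k, n_eval, ties, n_excl = naive_consistency(ff, ffpe, ids, fraction)
        assert (rec.k_consistent, rec.n_evaluated, rec.n_tied, rec.n_excluded) == (
            k, n_eval, ties, n_excl
        )

    def test_block_size_does_not_change_result(self, rng):
        ff = rng.lognormal(0, 1, 60)
        ffpe = ff * rng.lognormal(0, 0.4, 60)
        full = consistency_score(ff, ffpe, fraction=0.2)
        for block in (7, 16, 61):
            small = consistency_score(ff, ffpe, fraction=0.2, block=block)
            assert (small.k_consistent, small.n_evaluated) == (
                full.k_consistent, full.n_evaluated
            )


class TestCohortConsistency:
    def _identity_cohort(self, rng, n_genes=20, n_pairs=3):
        values = rng.lognormal(0, 1, (n_genes, n_pairs))
        genes = [f"G{i:02d}" for i in range(n_genes)]
        ff = ExpressionMatrix.from_arrays(values, genes, [f"F{i}" for i in range(n_pairs)])
        fp = ExpressionMatrix.from_arrays(values * 2, genes, [f"P{i}" for i in range(n_pairs)])
        return PairedCohort(ff=ff, ffpe=fp,
                            pairing=tuple((f"F{i}", f"P{i}") for i in range(n_pairs)))

    def test_identical_profiles_score_one_at_every_fraction(self, rng):
        report = cohort_consistency(self._identity_cohort(rng), (0.0, 0.1, 0.2))
        assert set(report.mean_scores().values()) == {1.0}

    def test_cohort_mean_is_arithmetic_mean_of_pair_scores(self, rng):
        cohort = self._identity_cohort(rng, n_genes=15, n_pairs=4)
        # perturb one FFPE sample so scores differ across pairs
        data = cohort.ffpe.data.copy()
        data.iloc[:, 0] = data.iloc[::-1, 0].to_numpy()
        cohort = PairedCohort(ff=cohort.ff,
                              ffpe=ExpressionMatrix(data), pairing=cohort.pairing)
        report = cohort_consistency(cohort, (0.0,))
        scores = [r.score for r in report.records]
        assert report.mean_scores()[0.0] == pytest.approx(np.mean(scores))

    def test_empty_pairing_rejected(self, rng):
        c = self._identity_cohort(rng)
        empty = PairedCohort(ff=c.ff, ffpe=c.ffpe, pairing=())
        with pytest.raises(ReoError):
            cohort_consistency(empty)

    def test_report_tsv_contains_per_pair_and_summary_rows(self, rng, tmp_path):
        report = cohort_consistency(self._identity_cohort(rng), (0.0, 0.1))
        out = tmp_path / "report.tsv"
        report.to_tsv(out)
        text = out.read_text()
        assert "__mean__" in text and "ff_id" in text
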