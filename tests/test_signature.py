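import numpy as np
import pandas as pd
import pytest

from reosig import (
    ExpressionMatrix,
    ReversalPairSignatureModel,
    Signature,
    SignaturePair,
    find_reversal_pairs,
    make_two_class_cohort,
    score_pair,
    score_pairs,
    select_signature,
)
from reosig.ranking import ReoError
from reosig.simulate import GeneratorConfig

from _naive import naive_avg_rank_diff_score, naive_reversal_pairs


def _matrix(values, genes, prefix="S"):
    values = np.asarray(values, float)
    return ExpressionMatrix.from_arrays(
        values, genes, [f"{prefix}{i}" for i in range(values.shape[1])]
    )


class TestFindReversalPairs:
    def test_perfect_reversal_included(self):
        c0 = _matrix([[10] * 10, [1] * 10], ["A", "B"])
        c1 = _matrix([[1] * 10, [10] * 10], ["A", "B"], prefix="T")
        out = find_reversal_pairs(c0, c1, 0.85)
        assert len(out) == 1
        p = out[0]
        assert (p.gene_a, p.gene_b) == ("A", "B")
        assert p.consistency_class0 == 1.0 and p.consistency_class1 == 1.0

    def test_exactly_at_threshold_excluded(self):
        # A > B in exactly 85% of 20 class-0 samples: strict > fails
        a = np.full(20, 10.0)
        b = np.full(20, 1.0)
        b[:3] = 20.0  # 17/20 = 0.85
        c0 = _matrix(np.vstack([a, b]), ["A", "B"])
        c1 = _matrix([[1] * 20, [10] * 20], ["A", "B"], prefix="T")
        assert find_reversal_pairs(c0, c1, 0.85) == []

    def test_matches_brute_force_enumeration_with_implants(self):
        cfg = GeneratorConfig(
            n_genes=15, n_samples=30, seed=3,
            reversal_pairs=(("G00002", "G00009", 2.0), ("G00004", "G00011", 2.0),
                            ("G00001", "G00013", 2.0)),
        )
        two = make_two_class_cohort(cfg)
        got = find_reversal_pairs(two.class0, two.class1, 0.85)
        expected = naive_reversal_pairs(
            two.class0.values, two.class1.values, two.class0.gene_ids, 0.85
        )
        got_map = {(p.gene_a, p.gene_b): (p.consistency_class0, p.consistency_class1)
                   for p in got}
        assert got_map.keys() == expected.keys()
        implanted = {(a, b) for a, b, _ in two.implanted}
        assert implanted <= set(got_map)
        for key, (c0, c1) in expected.items():
            assert got_map[key] == pytest.approx((c0, c1))

    def test_antisymmetric_in_class_arguments(self, rng):
        from conftest import random_matrix

        c0 = random_matrix(rng, 12, 25)
        c1 = random_matrix(rng, 12, 25)
        fwd = find_reversal_pairs(c0, c1, 0.6)
        rev = find_reversal_pairs(c1, c0, 0.6)
        assert {(p.gene_a, p.gene_b) for p in fwd} == {
            (p.gene_b, p.gene_a) for p in rev
        }


class TestScorePair:
    def test_constant_rank_diffs_square(self):
        r0 = pd.DataFrame([[5.0, 5.0], [1.0, 1.0]], index=["A", "B"])
        r1 = pd.DataFrame([[1.0, 1.0], [5.0, 5.0]], index=["A", "B"])
        p = SignaturePair("A", "B", 1.0, 1.0)
        assert score_pair(p, r0, r1) == 16.0

    def test_product_of_class_means(self):
        # class0 rank diffs {2, 4} -> mean 3; class1 {3, 5} -> mean 4
        r0 = pd.DataFrame([[3.0, 5.0], [1.0, 1.0]], index=["A", "B"])
        r1 = pd.DataFrame([[4.0, 6.0], [1.0, 1.0]], index=["A", "B"])
        p = SignaturePair("A", "B", 1.0, 1.0)
        assert score_pair(p, r0, r1) == 12.0

    def test_zero_mean_diff_annihilates(self):
        r0 = pd.DataFrame([[2.0], [2.0]], index=["A", "B"])
        r1 = pd.DataFrame([[1.0], [5.0]], index=["A", "B"])
        p = SignaturePair("A", "B", 1.0, 1.0)
        assert score_pair(p, r0, r1) == 0.0

    def test_score_pairs_ranks_whole_sample(self, rng):
        from conftest import random_matrix

        c0 = random_matrix(rng, 10, 6)
        c1 = random_matrix(rng, 10, 6)
        pairs = [SignaturePair("G002", "G007", 1.0, 1.0)]
        scored = score_pairs(pairs, c0, c1)
        expected = naive_avg_rank_diff_score(c0.values, c1.values, 2, 7)
        assert scored[0].score == pytest.approx(expected)


class TestSelectSignature:
    def _candidates(self, scores):
        return [
            SignaturePair(f"A{i}", f"B{i}", 1.0, 1.0, score=s)
            for i, s in enumerate(scores)
        ]

    def test_top_k_by_descending_score(self):
        sig = select_signature(self._candidates([9, 7, 7, 3]), k=3)
        assert [p.score for p in sig.pairs] == [9, 7, 7]

    def test_even_k_rejected(self):
        with pytest.raises(ReoError):
            select_signature(self._candidates([1, 2, 3, 4]), k=2)

    def test_k_exceeding_candidates_rejected(self):
        with pytest.raises(ReoError):
            select_signature(self._candidates([1, 2]), k=3)

    def test_k_equal_to_candidates_returns_all_sorted(self):
        sig = select_signature(self._candidates([1, 5, 3]), k=3)
        assert [p.score for p in sig.pairs] == [5, 3, 1]

    def test_score_ties_broken_lexicographically(self):
        pairs = [
            SignaturePair("Z", "Y", 1.0, 1.0, score=5.0),
            SignaturePair("A", "B", 1.0, 1.0, score=5.0),
            SignaturePair("M", "N", 1.0, 1.0, score=5.0),
        ]
        sig = select_signature(pairs, k=3)
        assert [p.gene_a for p in sig.pairs] == ["A", "M", "Z"]

    def test_product_ranking_equals_geometric_mean_ranking(self, rng):
        d0 = rng.uniform(0.1, 50, 40)
        d1 = rng.uniform(0.1, 50, 40)
        product = d0 * d1
        geomean = np.sqrt(d0 * d1)
        np.testing.assert_array_equal(np.argsort(product), np.argsort(geomean))


class TestModelFacade:
    def test_fit_recovers_implanted_pairs_and_summarizes(self):
        cfg = GeneratorConfig(n_genes=200, n_samples=40, seed=5,
                              n_reversal_pairs=3)
        two = make_two_class_cohort(cfg)
        model = ReversalPairSignatureModel(
            two.class0, two.class1, class0_name="cirrhosis", class1_name="hcc"
        )
        res = model.fit(k=3)
        assert {(p.gene_a, p.gene_b) for p in res.signature.pairs} == {
            (a, b) for a, b, _ in two.implanted
        }
        text = res.summary()
        assert "cirrhosis" in text and "avgRij" in text
        sens = res.training_sensitivities()
        assert set(sens) == {"cirrhosis", "hcc"}
        assert all(0 <= v <= 1 for v in sens.values())

    def test_signature_tsv_roundtrip(self, tmp_path):
        cfg = GeneratorConfig(n_genes=100, n_samples=30, seed=9,
                              n_reversal_pairs=3)
        two = make_two_class_cohort(cfg)
        res = ReversalPairSignatureModel(two.class0, two.class1).fit(k=3)
        path = tmp_path / "sig.tsv"
        res.signature.to_tsv(path)
        back = Signature.read_tsv(path)
        pd.testing.assert_frame_equal(
            back.to_frame(), res.signature.to_frame(), rtol=1e-9
        )
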