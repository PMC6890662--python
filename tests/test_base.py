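import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import basecomp as bc
from basecomp.base import WeightProfile, rank_genes, running_sums, preliminary_score
from basecomp.errors import DegenerateInputError, ValidationError

from conftest import naive_base


def make_rs(g, w):
    g = np.asarray(g, dtype=float)
    w = np.asarray(w, dtype=float)
    genes = np.array([f"x{i}" for i in range(len(g))], dtype=object)
    return bc.RankedSample(genes=genes, g=g, w=w)


class TestRunningSums:
    def test_hand_evaluated_distributions(self):
        f, b = running_sums(make_rs([4, 3, 2, 1], [1, 1, 0, 0]))
        np.testing.assert_allclose(f, [4 / 7, 1, 1, 1], atol=1e-15)
        np.testing.assert_allclose(b, [0, 0, 2 / 3, 1], atol=1e-15)

    def test_mirrored_weights_swap_roles(self):
        f, b = running_sums(make_rs([4, 3, 2, 1], [0, 0, 1, 1]))
        np.testing.assert_allclose(f, [0, 0, 2 / 3, 1], atol=1e-15)
        np.testing.assert_allclose(b, [4 / 7, 1, 1, 1], atol=1e-15)

    def test_uniform_weights_make_foreground_equal_background(self):
        g = np.random.default_rng(0).normal(size=20)
        f, b = running_sums(make_rs(g, np.full(20, 0.5)))
        np.testing.assert_allclose(f, b, atol=1e-15)

    def test_zero_denominator_names_the_degenerate_sum(self):
        with pytest.raises(DegenerateInputError, match="foreground"):
            running_sums(make_rs([1.0, 2.0], [0.0, 0.0]))
        with pytest.raises(DegenerateInputError, match="background"):
            running_sums(make_rs([1.0, 2.0], [1.0, 1.0]))


class TestPreliminaryScore:
    @pytest.mark.parametrize(
        "w, expected",
        [([1, 1, 0, 0], 1.0), ([0, 0, 1, 1], -1.0)],
    )
    def test_signed_extremes(self, w, expected):
        f, b = running_sums(make_rs([4, 3, 2, 1], w))
        assert preliminary_score(f, b) == pytest.approx(expected, abs=1e-12)

    def test_identical_distributions_score_zero(self):
        f = np.array([0.2, 0.5, 1.0])
        assert preliminary_score(f, f) == 0.0


class TestRankGenes:
    def test_ties_break_by_gene_identifier(self):
        prof = WeightProfile("p", pd.Series({"A": 1.0, "B": 0.0, "C": 0.0}))
        rs = rank_genes(pd.Series({"C": 1.0, "A": 2.0, "B": 2.0}), prof)
        assert list(rs.genes) == ["A", "B", "C"]

    def test_descending_order_with_negatives(self):
        prof = WeightProfile("p", pd.Series({"A": 1.0}))
        rs = rank_genes(pd.Series({"A": -1.0, "B": 3.0}), prof)
        assert list(rs.genes) == ["B", "A"]

    def test_unweighted_gene_defaults_to_background(self):
        prof = WeightProfile("p", pd.Series({"A": 0.7}))
        rs = rank_genes(pd.Series({"A": 1.0, "Z": 5.0}), prof)
        assert rs.w[list(rs.genes).index("Z")] == 0.0

    def test_empty_universe_intersection_errors(self):
        prof = WeightProfile("p", pd.Series({"A": 0.7}))
        with pytest.raises(DegenerateInputError):
            rank_genes(pd.Series({"A": 1.0}), prof, universe=pd.Index(["Q"]))


class TestOracleEquivalence:
    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(3, 51))
            g = rng.normal(size=n)
            w = rng.uniform(0, 1, size=n)
            ids = [f"x{i}" for i in range(n)]
            prof = WeightProfile("oracle", pd.Series(w, index=ids))
            rs = rank_genes(pd.Series(g, index=ids), prof)
            f, b = running_sums(rs)
            score = preliminary_score(f, b)
            nf, nb, nscore = naive_base(g, w)
            np.testing.assert_allclose(f, nf, atol=1e-12)
            np.testing.assert_allclose(b, nb, atol=1e-12)
            assert score == pytest.approx(nscore, abs=1e-12)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.floats(-50, 50, allow_nan=False),
            st.floats(0, 1, allow_nan=False),
        ),
        min_size=3,
        max_size=40,
    )
)
def test_distribution_invariants(data):
    """f and b are non-decreasing, end at 1, and the score lies in [-1, 1]."""
    g = np.array([d[0] for d in data])
    w = np.array([d[1] for d in data])
    if np.sum(np.abs(g) * w) == 0 or np.sum(np.abs(g) * (1 - w)) == 0:
        return
    f, b = running_sums(make_rs(g, w))
    assert (np.diff(f) >= -1e-15).all() and (np.diff(b) >= -1e-15).all()
    assert f[0] >= 0 and b[0] >= 0
    assert abs(f[-1] - 1) < 1e-12 and abs(b[-1] - 1) < 1e-12
    assert -1 - 1e-12 <= preliminary_score(f, b) <= 1 + 1e-12


class TestNormalizeScore:
    def test_same_seed_reproduces_scores(self):
        rng = np.random.default_rng(1)
        rs = make_rs(rng.normal(size=60), rng.uniform(0, 1, 60))
        a = bc.normalize_score(rs, n_perm=200, seed=9)
        b_ = bc.normalize_score(rs, n_perm=200, seed=9)
        assert a.normalized == b_.normalized and a.preliminary == b_.preliminary

    def test_too_few_permutations_rejected(self):
        rs = make_rs([3.0, 2.0, 1.0], [1.0, 0.0, 0.0])
        with pytest.raises(ValidationError):
            bc.normalize_score(rs, n_perm=50)

    def test_nes_mode_sign_stratified(self):
        rng = np.random.default_rng(2)
        rs = make_rs(rng.normal(size=80), rng.uniform(0, 1, 80))
        score = bc.normalize_score(rs, n_perm=200, seed=3, mode="nes")
        assert np.isfinite(score.normalized)
        assert np.sign(score.normalized) == np.sign(score.preliminary)


class TestScoreSamples:
    def test_one_score_per_sample_in_input_order(self, small_cohort):
        em = bc.median_normalize(small_cohort.expression)
        prof = WeightProfile("t", pd.Series(0.8, index=em.gene_ids[:20]))
        scores = bc.score_samples(em, prof, n_perm=100, seed=1)
        assert list(scores.index) == list(em.sample_ids)
        assert scores["normalized"].notna().all()

    def test_requires_median_centered_input(self, small_cohort):
        prof = WeightProfile("t", pd.Series(0.8, index=small_cohort.expression.gene_ids[:20]))
        with pytest.raises(ValidationError, match="median"):
            bc.score_samples(small_cohort.expression, prof, n_perm=100)

    def test_targets_at_top_of_ranking_score_positive(self):
        genes = pd.Index([f"g{i}" for i in range(100)], name="gene")
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(rng.normal(0, 1, (100, 12)), index=genes,
                            columns=[f"s{i}" for i in range(12)])
        vals.iloc[:10, :6] += 4.0  # targets dominate the ranking in half the samples
        em = bc.median_normalize(bc.ExpressionMatrix(vals))
        prof = WeightProfile("up", pd.Series(1.0, index=genes[:10]))
        scores = bc.score_samples(em, prof, n_perm=100, seed=2)
        boosted = scores["normalized"].iloc[:6]
        rest = scores["normalized"].iloc[6:]
        assert boosted.mean() > rest.mean()
        assert boosted.min() > 0


class TestMonotonicityDirection:
    def test_raising_high_weight_genes_increases_scores_on_average(self):
        rng = np.random.default_rng(3)
        deltas = []
        for _ in range(100):
            n = int(rng.integers(10, 50))
            ids = [f"x{i}" for i in range(n)]
            g = pd.Series(rng.normal(size=n), index=ids)
            w = pd.Series(rng.uniform(0, 1, size=n), index=ids)
            prof = WeightProfile("m", w)
            s1 = preliminary_score(*running_sums(rank_genes(g, prof)))
            g2 = g.copy()
            hi = w.index[w >= 0.8]
            g2[hi] = g2[hi] + rng.uniform(0, 2, len(hi))
            s2 = preliminary_score(*running_sums(rank_genes(g2, prof)))
            deltas.append(s2 - s1)
        assert np.mean(deltas) > 0

    def test_small_decreases_are_genuine_not_a_bug(self):
        """The signed-max-deviation statistic is not strictly monotone in
        foreground expression: inflating a foreground gene's magnitude grows
        the foreground normalizer and can lower f(i) at earlier ranks.  The
        implementation must agree with the brute-force definition on such a
        case rather than smooth it away."""
        g1 = np.array([10.0, 1.0, 0.5])
        g2 = np.array([10.0, 1.0, 0.9])
        w = np.array([1.0, 0.0, 1.0])
        s1 = preliminary_score(*running_sums(make_rs(g1, w)))
        s2 = preliminary_score(*running_sums(make_rs(g2, w)))
        assert s2 < s1  # raising a w=1 gene lowered the score
        assert s1 == pytest.approx(naive_base(g1, w)[2], abs=1e-12)
        assert s2 == pytest.approx(naive_base(g2, w)[2], abs=1e-12)


class TestWeightProfileValidation:
    def test_rejects_out_of_range_weights(self):
        with pytest.raises(ValidationError):
            WeightProfile("bad", pd.Series({"A": 1.5}))

    def test_rejects_all_zero_profile(self):
        with pytest.raises(ValidationError):
            WeightProfile("bad", pd.Series({"A": 0.0, "B": 0.0}))
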