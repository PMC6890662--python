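import numpy as np
import pandas as pd
import pytest

import basecomp as bc
from basecomp.base import WeightProfile
from basecomp.compartment import select_reference_genes
from basecomp.errors import DegenerateInputError, ValidationError


class TestAffinityMapping:
    @pytest.mark.parametrize(
        "p, w",
        [(1e-5, 0.5), (1.0, 0.0), (1e-12, 1.0), (1e-6, 0.6)],
    )
    def test_anchor_points(self, p, w):
        assert bc.affinity_from_pvalue(p) == pytest.approx(w, abs=1e-12)

    def test_monotone_non_increasing_in_p(self):
        ps = np.logspace(-15, 0, 200)
        ws = bc.affinity_from_pvalue(ps)
        assert (np.diff(ws) <= 1e-15).all()

    @pytest.mark.parametrize("p", [0.0, -1.0, 1.5])
    def test_domain_violations(self, p):
        with pytest.raises(ValidationError):
            bc.affinity_from_pvalue(p)


class TestSelectTargets:
    def test_threshold_keeps_high_affinity_genes(self):
        bt = pd.DataFrame({"gene": ["A", "B"], "p_value": [1e-6, 1e-3]})
        targets = bc.select_targets(bt, affinity_cutoff=0.5)
        assert dict(targets) == pytest.approx({"A": 0.6})

    def test_zero_cutoff_keeps_everything(self):
        bt = pd.DataFrame({"gene": ["A", "B"], "p_value": [1e-6, 0.9]})
        assert len(bc.select_targets(bt, affinity_cutoff=0.0)) == 2

    def test_empty_selection_suggests_cutoff(self):
        bt = pd.DataFrame({"gene": ["A"], "p_value": [0.5]})
        with pytest.raises(DegenerateInputError, match="cutoff"):
            bc.select_targets(bt, affinity_cutoff=0.5)


class TestPurityCorrelation:
    @staticmethod
    def make_em(rows: dict, n: int) -> bc.ExpressionMatrix:
        samples = [f"s{i}" for i in range(n)]
        return bc.ExpressionMatrix(
            pd.DataFrame(list(rows.values()), index=list(rows), columns=samples)
        )

    def test_perfect_monotone_tracking(self):
        purity = pd.Series(np.linspace(0.1, 0.9, 12), index=[f"s{i}" for i in range(12)])
        em = self.make_em({"up": purity.to_numpy(), "down": -purity.to_numpy()}, 12)
        scc = bc.purity_correlation(em, purity)
        assert scc["up"] == pytest.approx(1.0)
        assert scc["down"] == pytest.approx(-1.0)

    def test_independent_gene_has_small_scc(self):
        rng = np.random.default_rng(0)
        n = 1000
        samples = [f"s{i}" for i in range(n)]
        purity = pd.Series(rng.uniform(0, 1, n), index=samples)
        em = bc.ExpressionMatrix(
            pd.DataFrame([rng.normal(0, 1, n)], index=["g"], columns=samples)
        )
        assert abs(bc.purity_correlation(em, purity)["g"]) < 0.1

    def test_constant_gene_flagged_zero(self):
        purity = pd.Series(np.linspace(0, 1, 12), index=[f"s{i}" for i in range(12)])
        em = self.make_em({"flat": np.ones(12)}, 12)
        assert bc.purity_correlation(em, purity)["flat"] == 0.0

    def test_too_few_samples_rejected(self):
        purity = pd.Series([0.5] * 5, index=[f"s{i}" for i in range(5)])
        em = self.make_em({"g": np.ones(5)}, 5)
        with pytest.raises(ValidationError, match="10"):
            bc.purity_correlation(em, purity)


class TestPartitionTargets:
    def test_cutoff_rules(self):
        targets = pd.Series({"a": 0.6, "b": 0.7, "c": 0.8})
        scc = pd.Series({"a": 0.4, "b": -0.3, "c": 0.05})
        tumor, env, nonspec = bc.partition_targets(targets, scc)
        assert list(tumor.index) == ["a"]
        assert list(env.index) == ["b"]
        assert list(nonspec.index) == ["c"]

    def test_outputs_partition_input_exactly(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(50)]
        targets = pd.Series(rng.uniform(0.5, 1, 50), index=genes)
        scc = pd.Series(rng.uniform(-1, 1, 40), index=genes[:40])  # 10 missing
        tumor, env, nonspec = bc.partition_targets(targets, scc)
        recombined = pd.concat([tumor, env, nonspec]).sort_index()
        pd.testing.assert_series_equal(recombined, targets.sort_index())


class TestReferenceGenes:
    def test_magnitude_rule_without_cohort_size(self):
        scc = pd.Series({"a": 0.3, "b": 0.3, "c": 0.05, "d": -0.4})
        targets = pd.Series({"b": 0.7})
        bt = pd.DataFrame({"gene": ["a", "b"], "p_value": [10 ** -2.0, 10 ** -7.0]})
        pos, neg = select_reference_genes(scc, targets, bt)
        assert pos == {"a"}  # b is a target, c below cutoff
        assert neg == {"d"}

    def test_reference_sets_disjoint_from_targets(self, small_profile):
        all_targets = set(small_profile.all_targets.index)
        assert not (set(small_profile.pos_ref) & all_targets)
        assert not (set(small_profile.neg_ref) & all_targets)
        assert not (set(small_profile.pos_ref) & set(small_profile.neg_ref))

    def test_significance_filter_removes_weak_chance_correlations(self):
        rng = np.random.default_rng(2)
        n, n_samples = 2000, 200
        scc = pd.Series(rng.normal(0, 1 / np.sqrt(n_samples - 1), n),
                        index=[f"g{i}" for i in range(n)])
        scc.attrs["n_samples"] = n_samples
        targets = pd.Series(dtype=float)
        # null genes: the BH filter should exclude nearly everything the raw
        # magnitude rule would admit
        with pytest.raises(DegenerateInputError):
            select_reference_genes(scc, targets, None, ref_fdr=0.05)
        pos, neg = select_reference_genes(scc, targets, None, ref_fdr=None)
        assert len(pos) + len(neg) > 50  # raw rule admits many chance genes

    def test_empty_reference_set_is_an_error(self):
        scc = pd.Series({"a": 0.05, "b": -0.02})
        with pytest.raises(DegenerateInputError):
            select_reference_genes(scc, pd.Series(dtype=float), None, ref_fdr=None)


class TestCompartmentProfile:
    def test_overlapping_target_sets_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            bc.CompartmentProfile(
                tf_name="X",
                tumor_targets=pd.Series({"a": 0.6}),
                env_targets=pd.Series({"a": 0.7}),
                nonspecific_targets=pd.Series(dtype=float),
            )

    def test_reference_overlapping_targets_rejected(self):
        with pytest.raises(ValidationError, match="pos_ref"):
            bc.CompartmentProfile(
                tf_name="X",
                tumor_targets=pd.Series({"a": 0.6}),
                env_targets=pd.Series(dtype=float),
                nonspecific_targets=pd.Series(dtype=float),
                pos_ref={"a"},
            )

    def test_serialization_roundtrip(self, small_profile, tmp_path):
        path = tmp_path / "profile.tsv"
        bc.write_profile(small_profile, path)
        back = bc.read_profile(path)
        pd.testing.assert_series_equal(
            back.tumor_targets.sort_index(), small_profile.tumor_targets.sort_index()
        )
        assert back.pos_ref == small_profile.pos_ref
        assert back.ref_scc_cutoff == small_profile.ref_scc_cutoff
        assert back.ref_fdr == small_profile.ref_fdr


class TestInferActivities:
    def test_one_gte_triple_per_sample(self, small_cohort, small_profile):
        em = bc.median_normalize(small_cohort.expression)
        table = bc.infer_compartment_activities(em, small_profile, n_perm=100, seed=3)
        assert list(table.index) == list(em.sample_ids)
        assert list(table.columns) == ["G", "T", "E"]
        assert np.isfinite(table.to_numpy()).all()

    def test_t_scores_blind_to_env_target_expression(self, small_cohort, small_profile):
        """Permuting env-target expression must leave T scores bit-identical:
        the T and E scoring universes are disjoint by construction."""
        em = bc.median_normalize(small_cohort.expression)
        before = bc.infer_compartment_activities(em, small_profile, n_perm=100, seed=3)
        scrambled = em.values.copy()
        env_genes = [g for g in small_profile.env_targets.index if g in scrambled.index]
        rng = np.random.default_rng(9)
        scrambled.loc[env_genes] = rng.permutation(scrambled.loc[env_genes].to_numpy())
        em2 = bc.ExpressionMatrix(scrambled, normalized=True)
        after = bc.infer_compartment_activities(em2, small_profile, n_perm=100, seed=3)
        np.testing.assert_array_equal(before["T"].to_numpy(), after["T"].to_numpy())

    def test_low_target_coverage_names_the_set(self, small_cohort, small_profile):
        em = bc.median_normalize(small_cohort.expression)
        keep = [g for g in em.gene_ids if g not in small_profile.tumor_targets.index[:-1]]
        em_sub = bc.ExpressionMatrix(em.values.loc[keep], normalized=True)
        with pytest.raises(ValidationError, match="tumor targets"):
            bc.infer_compartment_activities(em_sub, small_profile, n_perm=100)

    def test_deterministic_under_seed(self, small_cohort, small_profile):
        em = bc.median_normalize(small_cohort.expression)
        a = bc.infer_compartment_activities(em, small_profile, n_perm=100, seed=5)
        b = bc.infer_compartment_activities(em, small_profile, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(a, b)
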