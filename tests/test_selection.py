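"""LDL-C preparation, relatedness pruning, PCs, LDL association and the
variant-selection cascades."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pleioscan as ps
from pleioscan import (
    compute_pcs,
    ld_group,
    ldl_association,
    pairwise_r2,
    prepare_ldl,
    prune_relatives,
    select_primary_variants,
    select_secondary_variants,
)


def meas(*rows):
    return pd.DataFrame(rows, columns=["person", "date", "value", "on_llm"])


class TestPrepareLdl:
    def test_median_of_pretreatment_values(self):
        m = meas((1, 0, 100, 0), (1, 1, 120, 0), (1, 2, 140, 0))
        assert prepare_ldl(m).loc[1] == 120

    def test_on_treatment_backcorrected(self):
        m = meas((1, 0, 110, 1), (1, 1, 120, 1), (1, 2, 130, 1))
        assert prepare_ldl(m).loc[1] == pytest.approx(160.0)  # 120 / 0.75

    def test_pretreatment_takes_precedence(self):
        m = meas((1, 0, 110, 0), (1, 1, 80, 1))
        assert prepare_ldl(m).loc[1] == 110

    def test_nonpositive_values_rejected(self):
        m = meas((1, 0, -5, 0), (1, 1, 100, 0))
        assert prepare_ldl(m).loc[1] == 100

    def test_llm_cancellation_recovers_latent(self):
        """With zero noise, /0.75 exactly undoes the on-treatment scaling."""
        cfg = ps.SimulationConfig(
            n_individuals=200, seed=3, ldl_sd=0.0, ldl_meas_sd=0.0,
            llm_probability=0.5,
            variant_specs=[ps.VariantSpec("rs1", "PCSK9", 0.3, ldl_beta=-8.0)],
            phecode_specs=[ps.PhecodeSpec(272.1, 0.2)],
        )
        from pleioscan.simulate import simulate_genotypes, simulate_ldl
        dosages, _, _ = simulate_genotypes(cfg)
        m, latent, on_llm = simulate_ldl(dosages, cfg)
        adj = prepare_ldl(m)
        only_on = on_llm[on_llm].index
        assert np.allclose(adj.loc[only_on], latent.loc[only_on])


class TestPruneRelatives:
    PAIRS = pd.DataFrame({"person_a": [1], "person_b": [2], "pi_hat": [0.6]})

    def test_flagged_pair_loses_one_member(self):
        kept = prune_relatives(self.PAIRS, range(5), threshold=0.5, seed=0)
        assert len(kept) == 4
        assert len({1, 2} & set(kept)) == 1

    def test_below_threshold_both_retained(self):
        pairs = self.PAIRS.assign(pi_hat=0.4)
        kept = prune_relatives(pairs, range(5), threshold=0.5, seed=0)
        assert len(kept) == 5

    def test_deterministic_given_seed(self):
        pairs = pd.DataFrame({"person_a": [1, 3, 5], "person_b": [2, 4, 1],
                              "pi_hat": [0.6, 0.9, 0.55]})
        a = prune_relatives(pairs, range(8), seed=42)
        b = prune_relatives(pairs, range(8), seed=42)
        assert list(a) == list(b)

    def test_cascades_over_relatedness_graph(self):
        # chain 1-2, 2-3: the retained set must contain no flagged pair
        pairs = pd.DataFrame({"person_a": [1, 2], "person_b": [2, 3],
                              "pi_hat": [0.9, 0.9]})
        for seed in range(10):
            kept = set(prune_relatives(pairs, range(5), seed=seed))
            assert not ({1, 2} <= kept) and not ({2, 3} <= kept)


class TestPcs:
    def test_two_subpopulations_separated_by_pc1(self):
        rng = np.random.default_rng(0)
        n, m = 400, 40
        p1 = rng.uniform(0.1, 0.4, m)
        p2 = np.clip(p1 + rng.choice([-0.25, 0.25], m), 0.05, 0.9)
        X = np.vstack([
            rng.binomial(2, p1, (n // 2, m)),
            rng.binomial(2, p2, (n // 2, m)),
        ]).astype(float)
        scores, _ = compute_pcs(pd.DataFrame(X), n_pcs=2)
        g1, g2 = scores.iloc[: n // 2, 0], scores.iloc[n // 2:, 0]
        within = max(g1.std(), g2.std())
        assert abs(g1.mean() - g2.mean()) > 3 * within

    def test_variance_explained_non_increasing(self, small_cohort):
        _, explained = compute_pcs(small_cohort.dosages, n_pcs=2)
        assert explained[0] >= explained[1] >= 0

    def test_first_pc_consistent_across_npcs(self, small_cohort):
        s1, _ = compute_pcs(small_cohort.dosages, n_pcs=1)
        s2, _ = compute_pcs(small_cohort.dosages, n_pcs=2)
        np.testing.assert_allclose(s1["PC1"], s2["PC1"], atol=1e-8)

    def test_constant_matrix_rejected(self):
        X = pd.DataFrame(np.ones((10, 3)))
        with pytest.raises(ValueError):
            compute_pcs(X, n_pcs=2)


class TestLdlAssociation:
    def test_matches_normal_equations_on_ten_rows(self):
        rng = np.random.default_rng(1)
        d = pd.Series(rng.binomial(2, 0.3, 10).astype(float))
        y = pd.Series(130 - 5 * d + rng.normal(0, 10, 10))
        fit = ldl_association(d, y, min_n=10)
        X = np.column_stack([np.ones(10), d])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        assert fit.beta == pytest.approx(beta_hat[1], abs=1e-8)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(2)
        ps_ = []
        for _ in range(200):
            d = pd.Series(rng.binomial(2, 0.3, 100).astype(float))
            y = pd.Series(rng.normal(130, 30, 100))
            ps_.append(ldl_association(d, y).p)
        frac = np.mean(np.array(ps_) < 0.05)
        assert 0.01 <= frac <= 0.10

    def test_rank_deficient_design_flagged(self):
        d = pd.Series(np.tile([0.0, 1.0], 20))
        y = pd.Series(np.random.default_rng(0).normal(size=40))
        cov = pd.DataFrame({"dup": d})  # duplicates the dosage column
        fit = ldl_association(d, y, cov)
        assert not fit.estimable

    def test_too_few_observations_raise(self):
        with pytest.raises(ValueError):
            ldl_association(pd.Series([0, 1, 2.0]), pd.Series([1, 2, 3.0]))


class TestPairwiseR2:
    def test_identical_vectors(self):
        v = np.array([0, 1, 2, 0, 1, 2.0])
        assert pairwise_r2(v, v) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = np.array([0, 1, 2, 0, 1, 2.0])
        b = np.array([2, 1, 0, 2, 1, 0.0])
        assert pairwise_r2(a, b) == pytest.approx(1.0)

    def test_hand_computed_zero(self):
        assert pairwise_r2(np.array([0, 0, 1, 1.0]),
                           np.array([0, 1, 0, 1.0])) == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pairwise_r2(np.ones(4), np.array([0, 1, 0, 1.0]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.binomial(2, 0.4, 50).astype(float)
        b = rng.binomial(2, 0.4, 50).astype(float)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return
        assert 0.0 <= pairwise_r2(a, b) <= 1.0 + 1e-12


class TestPrimaryCascade:
    def test_hand_traced_survivor_set(self, cascade_fixture):
        dosages, variants, stats = cascade_fixture
        selected, audit = select_primary_variants(variants, dosages, stats)
        assert selected == ["v1"]
        assert not audit.loc["v2", "ld_ok"]          # pruned against v1
        assert not audit.loc["v3", "imputation_ok"]
        assert not audit.loc["v4", "maf_ok"]
        assert not audit.loc["v5", "ldl_ok"]
        assert not audit.loc["v6", "in_region"]

    def test_region_boundaries_inclusive(self):
        region = ps.GENE_REGIONS["PCSK9"]
        assert region.contains("1", 55505647)
        assert region.contains("1", 55505149) and region.contains("1", 55530526)
        assert not region.contains("1", 55505148)

    def test_survivors_satisfy_all_thresholds(self, recovery_run):
        cohort, out = recovery_run
        audit = out.selection_audit
        sel = audit[audit.selected]
        assert (sel["maf"] > 0.01).all()
        assert (sel["ldl_p"] < 5e-8).all()
        assert (cohort.variants.loc[sel.index, "imputation_r2"] > 0.4).all()
        rsids = sel.index.tolist()
        for i, a in enumerate(rsids):
            for b in rsids[i + 1:]:
                assert pairwise_r2(cohort.dosages[a], cohort.dosages[b]) < 0.3

    def test_ld_pruning_keeps_strongest_association(self):
        """Within a mutually-linked pair the smaller LDL p-value wins
        regardless of input order."""
        rng = np.random.default_rng(7)
        base = rng.binomial(2, 0.3, 300).astype(float)
        dosages = pd.DataFrame({"a": base, "b": base})
        variants = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [55505200, 55505300],
             "annotation": ["intron", "intron"], "imputation_r2": [0.9, 0.9]},
            index=pd.Index(["a", "b"], name="rsid"))
        stats = pd.DataFrame({"p": [1e-10, 1e-30]}, index=variants.index)
        selected, _ = select_primary_variants(variants, dosages, stats)
        assert selected == ["b"]
        selected2, _ = select_primary_variants(
            variants.iloc[::-1], dosages, stats)
        assert selected2 == ["b"]

    def test_empty_result_is_valid(self, cascade_fixture):
        dosages, variants, stats = cascade_fixture
        cfg = ps.PipelineConfig(maf_min=0.499)
        selected, _ = select_primary_variants(variants, dosages, stats, config=cfg)
        assert selected == []


class TestSecondaryCascade:
    def _fixture(self):
        rng = np.random.default_rng(3)
        dosages = pd.DataFrame({
            "m_null": rng.binomial(2, 0.2, 300).astype(float),
            "m_assoc": rng.binomial(2, 0.2, 300).astype(float),
            "intron": rng.binomial(2, 0.2, 300).astype(float),
        })
        variants = pd.DataFrame(
            {"chrom": ["1"] * 3, "pos": [55505200, 55505300, 55505400],
             "annotation": ["missense", "missense", "intron"],
             "imputation_r2": [0.9, 0.9, 0.9]},
            index=pd.Index(dosages.columns, name="rsid"))
        stats = pd.DataFrame({"p": [0.3, 1e-9, 0.3]}, index=variants.index)
        return dosages, variants, stats

    def test_only_unassociated_missense_selected(self):
        dosages, variants, stats = self._fixture()
        selected, audit = select_secondary_variants(variants, dosages, stats)
        assert selected == ["m_null"]
        assert not audit.loc["m_assoc", "ldl_ok"]
        assert not audit.loc["intron", "annotation_ok"]


class TestLdGroup:
    def test_isolated_index_yields_empty(self):
        rng = np.random.default_rng(5)
        dosages = pd.DataFrame({
            "idx": rng.binomial(2, 0.3, 500).astype(float),
            "far": rng.binomial(2, 0.3, 500).astype(float),
        })
        out = ld_group(dosages, "idx")
        assert out.empty

    def test_exact_copies_form_one_tight_group(self):
        rng = np.random.default_rng(6)
        base = rng.binomial(2, 0.3, 500).astype(float)
        mix = np.where(rng.random(500) < 0.75, base, rng.binomial(2, 0.3, 500))
        dosages = pd.DataFrame({"idx": mix, "c1": base, "c2": base, "c3": base})
        out = ld_group(dosages, "idx")
        assert set(out.index) == {"c1", "c2", "c3"}
        assert out["group"].nunique() == 1

    def test_two_clusters_resolved(self):
        """Two near-copies of the index and two near-copies of a blended
        vector: linked set of four, split into two tight groups."""
        rng = np.random.default_rng(9)
        n = 4000
        idx = rng.binomial(2, 0.3, n).astype(float)

        def near_copy(v):
            flip = rng.random(n) < 0.01
            return np.where(flip, rng.binomial(2, 0.3, n), v).astype(float)

        blend = np.where(rng.random(n) < 0.75, idx, rng.binomial(2, 0.3, n)).astype(float)
        dosages = pd.DataFrame({
            "idx": idx,
            "a0": near_copy(idx), "a1": near_copy(idx),
            "b0": near_copy(blend), "b1": near_copy(blend),
        })
        out = ld_group(dosages, "idx", r2_tight=0.9)
        assert set(out.index) == {"a0", "a1", "b0", "b1"}
        partition = {frozenset(g) for g in out.groupby("group").groups.values()}
        assert partition == {frozenset({"a0", "a1"}), frozenset({"b0", "b1"})}

    def test_constant_index_rejected(self):
        dosages = pd.DataFrame({"idx": np.zeros(10), "a": np.arange(10.0)})
        with pytest.raises(ValueError):
            ld_group(dosages, "idx")
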