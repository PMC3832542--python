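"""Tests for MAF filtering, genotype PCA, the additive scan, genomic lambda
and the min-p permutation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rstab
from rstab.datatypes import GenotypeMatrix


def make_genotypes(dosages, mafs=None, chrom="chr1"):
    d = np.atleast_2d(np.asarray(dosages, dtype=float))
    snp_ids = pd.Index([f"s{i}" for i in range(d.shape[0])], name="snp_id")
    sample_ids = pd.Index([f"i{j}" for j in range(d.shape[1])], name="sample_id")
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, d.shape[0] + 1) * 1000,
         "major": "A", "minor": "G"},
        index=snp_ids,
    )
    return GenotypeMatrix(pd.DataFrame(d, index=snp_ids, columns=sample_ids),
                          snps, pd.DataFrame(index=sample_ids))


class TestMafFilter:
    def test_boundary_maf_removed(self):
        # 1 minor allele over 50 samples: MAF exactly 0.01 -> excluded
        row_at_boundary = [1.0] + [0.0] * 49
        keep_row = [1.0, 1.0] + [0.0] * 48
        g = make_genotypes([row_at_boundary, keep_row])
        out = rstab.maf_filter(g, 0.01)
        assert list(out.dosages.index) == ["s1"]

    def test_monomorphic_removed(self):
        g = make_genotypes([[0, 0, 0, 0], [0, 0, 1, 1]])
        out = rstab.maf_filter(g, 0.01)
        assert list(out.dosages.index) == ["s1"]

    def test_hand_counted_maf_retained(self):
        g = make_genotypes([[0, 0, 1, 1]])
        assert g.maf().iloc[0] == pytest.approx(0.25)
        assert rstab.maf_filter(g, 0.01).n_snps == 1

    def test_all_removed_is_error(self):
        g = make_genotypes([[0, 0, 0, 0]])
        with pytest.raises(ValueError):
            rstab.maf_filter(g, 0.01)

    def test_maf_uses_nonmissing_only(self):
        g = make_genotypes([[np.nan, np.nan, 1, 1]])
        assert g.maf().iloc[0] == pytest.approx(0.5)


class TestGenotypePCA:
    def test_components_orthogonal(self, tiny_study):
        genotypes, _, _ = tiny_study
        pcs = rstab.genotype_pca(genotypes, 4)
        gram = pcs.to_numpy().T @ pcs.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0.0, atol=1e-6 * np.abs(gram).max())

    def test_constant_genotypes_give_zero_pcs(self):
        g = make_genotypes(np.ones((10, 6)))
        pcs = rstab.genotype_pca(g, 2)
        assert np.allclose(pcs.to_numpy(), 0.0)

    def test_k_too_large_rejected(self):
        g = make_genotypes([[0, 1, 2, 1]])
        with pytest.raises(ValueError):
            rstab.genotype_pca(g, 3)

    def test_missing_dosages_mean_imputed(self):
        d = np.array([[0, 1, 2, 1, np.nan], [2, 1, 0, np.nan, 1]], dtype=float)
        pcs = rstab.genotype_pca(make_genotypes(d), 1)
        assert np.isfinite(pcs.to_numpy()).all()


class TestAdditiveRegression:
    def test_perfect_fit_flagged(self):
        dosage = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        res = rstab.additive_regression(2 * dosage + 7, dosage)
        assert res.beta == pytest.approx(2.0)
        assert res.se == pytest.approx(0.0)
        assert res.flag == "zero_residual"

    def test_orthogonal_phenotype_gives_zero_beta(self):
        dosage = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        phenotype = np.array([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])  # orthogonal to centered dosage
        res = rstab.additive_regression(phenotype, dosage)
        assert res.beta == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_oracle(self):
        dosage = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        phenotype = np.array([1.0, 1.9, 3.2, 0.8, 2.1, 3.0])
        res = rstab.additive_regression(phenotype, dosage)
        # independent closed form: slope = cov/var, t from residual SS
        gc = dosage - dosage.mean()
        beta = float(gc @ phenotype / (gc @ gc))
        alpha = phenotype.mean() - beta * dosage.mean()
        resid = phenotype - alpha - beta * dosage
        s2 = float(resid @ resid) / (len(dosage) - 2)
        se = np.sqrt(s2 / (gc @ gc))
        t = beta / se
        p = 2 * stats.t.sf(abs(t), len(dosage) - 2)
        assert res.beta == pytest.approx(beta)
        assert res.se == pytest.approx(se)
        assert res.p_value == pytest.approx(p)

    def test_matches_statsmodels_with_covariates(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, 30).astype(float)
        cov = rng.normal(size=(30, 2))
        y = 0.5 * dosage + cov @ [1.0, -0.5] + rng.normal(size=30)
        res = rstab.additive_regression(y, dosage, cov)
        fit = sm.OLS(y, sm.add_constant(np.column_stack([dosage, cov]))).fit()
        assert res.beta == pytest.approx(fit.params[1])
        assert res.se == pytest.approx(fit.bse[1])
        assert res.p_value == pytest.approx(fit.pvalues[1])

    def test_constant_dosage_flagged(self):
        res = rstab.additive_regression([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        assert res.flag == "constant_dosage"
        assert np.isnan(res.p_value)

    def test_missing_dosage_dropped_pairwise(self):
        dosage = np.array([0, 1, 2, np.nan, 1, 2], dtype=float)
        y = np.array([1.0, 2.0, 3.0, 99.0, 2.2, 2.9])
        res = rstab.additive_regression(y, dosage)
        assert res.n_used == 5


class TestGwasScan:
    def test_fast_path_equals_per_snp_regression(self, tiny_study):
        genotypes, halflife, expr = tiny_study
        scores = rstab.rs_score(expr, rstab.classify_genes(halflife))
        filtered = rstab.maf_filter(genotypes)
        pcs = rstab.genotype_pca(filtered, 3)
        table = rstab.gwas_scan(filtered, scores, pcs)
        cov = pcs.loc[scores.index].to_numpy()
        for snp_id in table.index[:10]:
            res = rstab.additive_regression(
                scores["rs_score"].to_numpy(),
                filtered.dosages.loc[snp_id, scores.index].to_numpy(),
                cov,
            )
            assert table.loc[snp_id, "beta"] == pytest.approx(res.beta)
            assert table.loc[snp_id, "p_value"] == pytest.approx(res.p_value)

    def test_pvalues_invariant_to_affine_phenotype(self, tiny_study):
        genotypes, halflife, expr = tiny_study
        scores = rstab.rs_score(expr, rstab.classify_genes(halflife))
        filtered = rstab.maf_filter(genotypes)
        a = rstab.gwas_scan(filtered, scores, None)
        rescaled = scores.copy()
        rescaled["rs_score"] = 3.5 * rescaled["rs_score"] - 11.0
        b = rstab.gwas_scan(filtered, rescaled, None)
        assert np.allclose(a["p_value"], b["p_value"])

    def test_causal_snp_is_top_hit(self):
        cfg = rstab.SimulationConfig(n_samples=100, n_pops=2, fst=0.1, n_snps=500,
                                     n_genes=500, effect_size=0.15,
                                     causal_snp_index=0, seed=1)
        g = rstab.simulate_genotypes(cfg)
        hl = rstab.simulate_halflife_table(cfg)
        expr = rstab.simulate_expression(g, hl, cfg)
        scores = rstab.rs_score(expr, rstab.classify_genes(hl))
        filtered = rstab.maf_filter(g)
        table = rstab.gwas_scan(filtered, scores, rstab.genotype_pca(filtered, 5))
        assert table.index[0] == "snp00000"
        assert table["bonferroni_p"].iloc[0] < 0.05

    def test_bonferroni_column(self, tiny_study):
        genotypes, halflife, expr = tiny_study
        scores = rstab.rs_score(expr, rstab.classify_genes(halflife))
        filtered = rstab.maf_filter(genotypes)
        table = rstab.gwas_scan(filtered, scores, None)
        m = len(table)
        assert np.allclose(table["bonferroni_p"],
                           np.minimum(table["p_value"] * m, 1.0))

    def test_no_overlap_rejected(self, tiny_study):
        genotypes, halflife, expr = tiny_study
        scores = rstab.rs_score(expr, rstab.classify_genes(halflife))
        scores.index = ["x" + s for s in scores.index]
        with pytest.raises(ValueError, match="overlap"):
            rstab.gwas_scan(genotypes, scores, None)


class TestGenomicLambda:
    def test_median_null_p_gives_one(self):
        assert rstab.genomic_lambda([0.5] * 99) == pytest.approx(1.0)

    def test_uniform_draws_near_one(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100_000)
        assert rstab.genomic_lambda(p) == pytest.approx(1.0, abs=0.02)

    def test_halved_pvalues_inflate(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=10_000)
        assert rstab.genomic_lambda(p / 2) > 1.0

    @pytest.mark.parametrize("bad", [[], [0.0, 0.5], [1.5]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            rstab.genomic_lambda(bad)


class TestPermutationMinP:
    @pytest.fixture
    def small_scan(self):
        cfg = rstab.SimulationConfig(n_samples=25, n_pops=1, fst=0.0, n_snps=50,
                                     n_genes=100, causal_snp_index=None, seed=4)
        g = rstab.simulate_genotypes(cfg)
        hl = rstab.simulate_halflife_table(cfg)
        expr = rstab.simulate_expression(g, hl, cfg)
        scores = rstab.rs_score(expr, rstab.classify_genes(hl))
        return rstab.maf_filter(g), scores

    def test_counting_rule(self, small_scan):
        genotypes, scores = small_scan
        res = rstab.permutation_minp(genotypes, scores, None, n_perm=20, seed=0)
        expected = np.sum(res.null_min_p <= res.observed_min_p) / 20
        assert res.permutation_p == pytest.approx(expected)
        assert len(res.null_min_p) == 20

    def test_extremes(self, small_scan):
        genotypes, scores = small_scan
        res = rstab.permutation_minp(genotypes, scores, None, n_perm=5, seed=1)
        # forcing the observed min below/above every null value drives p to 0/1
        forced_low = rstab.PermutationResult(0.0, res.null_min_p, 5, 1)
        assert forced_low.permutation_p in (0.0, np.sum(res.null_min_p == 0.0) / 5)
        forced_high = rstab.PermutationResult(1.0, res.null_min_p, 5, 1)
        assert forced_high.permutation_p == 1.0

    def test_single_permutation(self, small_scan):
        genotypes, scores = small_scan
        res = rstab.permutation_minp(genotypes, scores, None, n_perm=1, seed=2)
        assert res.permutation_p in (0.0, 1.0)

    def test_seed_reproducible(self, small_scan):
        genotypes, scores = small_scan
        a = rstab.permutation_minp(genotypes, scores, None, n_perm=10, seed=3)
        b = rstab.permutation_minp(genotypes, scores, None, n_perm=10, seed=3)
        assert np.array_equal(a.null_min_p, b.null_min_p)

    def test_zero_reported_as_bound_in_summary(self, small_scan):
        res = rstab.PermutationResult(1e-12, np.linspace(0.1, 0.9, 10), 10, 0)
        assert res.permutation_p == 0.0
        assert "<0.1" in res.summary()

    def test_invalid_nperm_rejected(self, small_scan):
        genotypes, scores = small_scan
        with pytest.raises(ValueError):
            rstab.permutation_minp(genotypes, scores, None, n_perm=0, seed=0)
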