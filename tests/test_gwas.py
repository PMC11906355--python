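import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from plasmapqtl import gwas, simdata
from plasmapqtl.gwas import (assoc_scan, assoc_scan_matrix, hwe_pvalue,
                             lambda_gc, qc_genotypes)
from plasmapqtl.io_formats import CohortBundle


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        # (810, 180, 10) are the exact HWE counts at allele frequency 0.1
        assert hwe_pvalue(810, 180, 10) == pytest.approx(1.0, abs=1e-9)

    def test_no_heterozygotes_is_extreme(self):
        # expected (250, 500, 250) -> chi2 = 250 + 500 + 250 = 1000
        p = hwe_pvalue(500, 0, 500)
        assert p < 1e-100


def _bundle_from_genotypes(geno: pd.DataFrame) -> CohortBundle:
    m = geno.shape[1]
    variants = pd.DataFrame({
        "chrom": "1", "pos": np.arange(1, m + 1) * 1000,
        "ref": "A", "alt": "G", "consequence": "intergenic",
        "gene_id": "", "aa_pos": np.nan,
    }, index=pd.Index(geno.columns, name="variant_id"))
    n = geno.shape[0]
    idx = geno.index
    rng = np.random.default_rng(0)
    prot = pd.DataFrame({"PROT0": rng.normal(size=n)}, index=idx)
    genes = pd.DataFrame({"gene_id": ["G0"], "chrom": ["1"], "tss": [500],
                          "strand": ["+"]},
                         index=pd.Index(["PROT0"], name="protein_id"))
    pmap = pd.DataFrame({"protein_id": ["PROT0"], "aa_start": [1],
                         "aa_end": [10]},
                        index=pd.Index(["PROT0_pep1"], name="peptide_id"))
    pep = pd.DataFrame({"PROT0_pep1": rng.normal(size=n)}, index=idx)
    cov = pd.DataFrame({"age": 10.0, "sex": 0.0, "bmi_sds": 0.0,
                        "obesity": 0.0, "puberty": 0.0, "storage": 1.0,
                        "pc1": 0.0}, index=idx)
    return CohortBundle(genotypes=geno, variants=variants, proteins=prot,
                        protein_genes=genes, peptides=pep, peptide_map=pmap,
                        covariates=cov)


class TestQcGenotypes:
    def test_maf_boundary(self):
        rng = np.random.default_rng(0)
        n = 1_000
        cols = {
            "low": rng.binomial(2, 0.049, n).astype(float),
            "high": rng.binomial(2, 0.051, n).astype(float),
            "mid": rng.binomial(2, 0.3, n).astype(float),
        }
        # force exact allele counts: low -> maf 0.049, high -> 0.051
        low = np.zeros(n); low[:98] = 1.0
        high = np.zeros(n); high[:102] = 1.0
        cols["low"], cols["high"] = low, high
        geno = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
        bundle = _bundle_from_genotypes(geno)
        out, report = qc_genotypes(bundle, hwe_p_min=0.0)
        assert "low" not in out.genotypes.columns
        assert "high" in out.genotypes.columns
        assert report.variants_dropped_maf == 1

    def test_hwe_violation_removed(self):
        n = 1_000
        col = np.array([0.0] * 500 + [2.0] * 500)
        ok = np.random.default_rng(1).binomial(2, 0.3, n).astype(float)
        geno = pd.DataFrame({"bad": col, "ok": ok},
                            index=[f"s{i}" for i in range(n)])
        out, report = qc_genotypes(_bundle_from_genotypes(geno))
        assert "bad" not in out.genotypes.columns
        assert report.variants_dropped_hwe == 1

    def test_call_rate_filters(self):
        rng = np.random.default_rng(2)
        n = 200
        good = rng.binomial(2, 0.3, n).astype(float)
        sparse = good.copy(); sparse[:20] = np.nan       # 90% call rate
        geno = pd.DataFrame({"sparse": sparse, "g1": good,
                             "g2": rng.binomial(2, 0.4, n).astype(float)},
                            index=[f"s{i}" for i in range(n)])
        # one sample missing most genotypes
        geno.iloc[5, 1:] = np.nan
        out, report = qc_genotypes(_bundle_from_genotypes(geno))
        assert "sparse" not in out.genotypes.columns
        assert "s5" not in out.genotypes.index
        assert report.variants_dropped_call_rate == 1
        assert report.samples_dropped_call_rate == 1

    def test_all_removed_raises(self):
        geno = pd.DataFrame({"v": [0.0] * 10}, index=[f"s{i}" for i in range(10)])
        with pytest.raises(ValueError, match="every variant"):
            qc_genotypes(_bundle_from_genotypes(geno))


class TestAssocScan:
    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(20, 60))
            g = rng.binomial(2, 0.3, n).astype(float)
            y = 0.3 * g + rng.normal(size=n)
            beta, se, p = assoc_scan_matrix(g[:, None], y)
            fit = sm.OLS(y, sm.add_constant(g)).fit()
            assert beta[0] == pytest.approx(fit.params[1], abs=1e-10)
            assert se[0] == pytest.approx(fit.bse[1], abs=1e-10)
            assert p[0] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_missing_dosage_pairwise_complete(self):
        rng = np.random.default_rng(8)
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        g[:25] = np.nan
        y = 0.5 * np.nan_to_num(g) + rng.normal(size=n)
        beta, se, p = assoc_scan_matrix(g[:, None], y)
        obs = np.isfinite(g)
        fit = sm.OLS(y[obs], sm.add_constant(g[obs])).fit()
        assert beta[0] == pytest.approx(fit.params[1], abs=1e-10)
        assert se[0] == pytest.approx(fit.bse[1], abs=1e-10)

    def test_perfect_fit_underflow_guarded(self):
        g = np.array([0.0, 1.0, 2.0] * 20)
        beta, se, p = assoc_scan_matrix(g[:, None], g.copy())
        assert beta[0] == pytest.approx(1.0)
        assert p[0] == gwas.P_FLOOR

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            assoc_scan_matrix(np.ones((10, 1)), np.ones(10))

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(9)
        n, m = 500, 10_000
        G = rng.binomial(2, 0.3, (n, m)).astype(float)
        y = rng.normal(size=n)
        _, _, p = assoc_scan_matrix(G, y)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_zero_maf_variant_skipped(self, tiny_cohort):
        geno = tiny_cohort.genotypes.copy()
        geno.iloc[:, 0] = 0.0
        bundle = CohortBundle(
            genotypes=geno, variants=tiny_cohort.variants,
            proteins=tiny_cohort.proteins,
            protein_genes=tiny_cohort.protein_genes,
            peptides=tiny_cohort.peptides, peptide_map=tiny_cohort.peptide_map,
            covariates=tiny_cohort.covariates)
        y = np.random.default_rng(0).normal(size=bundle.n_samples)
        recs = assoc_scan(bundle, y, "PROT0")
        assert geno.columns[0] not in {r.variant_id for r in recs}


class TestLambdaGc:
    def test_all_half_is_exactly_one(self):
        assert lambda_gc([0.5] * 7) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_p_near_one(self):
        p = np.random.default_rng(10).random(100_000)
        assert 0.98 < lambda_gc(p) < 1.02

    def test_halving_p_inflates(self):
        p = np.random.default_rng(11).random(1_000)
        assert lambda_gc(p / 2) > lambda_gc(p)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lambda_gc([])
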