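import numpy as np
import pandas as pd
import pytest

from plasmapqtl import pqtl, simdata
from plasmapqtl.gwas import AssociationRecord
from plasmapqtl.pqtl import (PqtlRecord, classify_cis_trans, clump,
                             conditional_scan, ld_r2, study_wide_threshold)


def brute_force_clump(pvals, positions, genotypes, r2_min=0.2,
                      window_bp=1e6, p_max=5e-8):
    """Literal restatement of the clumping definition, no shared code paths."""
    sig = [i for i, p in enumerate(pvals) if p < p_max]
    assigned = set()
    clumps = []
    while True:
        candidates = [i for i in sig if i not in assigned]
        if not candidates:
            break
        lead = sorted(candidates, key=lambda i: (pvals[i], positions[i]))[0]
        members = [lead]
        for j in candidates:
            if j == lead:
                continue
            if abs(positions[j] - positions[lead]) > window_bp:
                continue
            r = np.corrcoef(genotypes[:, lead], genotypes[:, j])[0, 1]
            if r * r > r2_min:
                members.append(j)
        assigned |= set(members)
        clumps.append((lead, frozenset(members)))
    return clumps


def _records(pvals):
    return [AssociationRecord(f"v{i}", "P", "protein", 1.0, 0.1, p, 100, 0.3)
            for i, p in enumerate(pvals)]


def _geno_df(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"v{j}" for j in range(arr.shape[1])],
                        index=[f"s{i}" for i in range(arr.shape[0])])


class TestLdR2:
    def test_self_is_one(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self, rng):
        a = rng.binomial(2, 0.3, 10_000).astype(float)
        b = rng.binomial(2, 0.3, 10_000).astype(float)
        assert ld_r2(a, b) < 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            ld_r2(np.ones(10), np.arange(10.0))


class TestClump:
    def test_single_significant_variant(self, rng):
        geno = _geno_df(rng.binomial(2, 0.3, (50, 3)))
        pos = pd.Series([1000, 2000, 3000], index=geno.columns)
        out = clump(_records([1e-10, 0.5, 0.9]), geno, pos)
        assert len(out) == 1
        assert out[0].lead_variant == "v0"
        assert out[0].clump_members == ["v0"]

    def test_ld_partner_joins_independent_stays(self, rng):
        n = 2_000
        g0 = rng.binomial(2, 0.3, n).astype(float)
        g1 = g0.copy()
        flip = rng.random(n) < 0.2           # r2 ~ 0.6 with g0
        g1[flip] = rng.binomial(2, 0.3, flip.sum())
        g2 = rng.binomial(2, 0.3, n).astype(float)
        geno = _geno_df(np.column_stack([g0, g1, g2]))
        pos = pd.Series([1_000, 2_000, 3_000], index=geno.columns)
        out = clump(_records([1e-10, 1e-9, 1e-8]), geno, pos)
        leads = [c.lead_variant for c in out]
        assert leads == ["v0", "v2"]
        assert set(out[0].clump_members) == {"v0", "v1"}

    def test_window_rule_splits_distant_ld(self, rng):
        n = 500
        g0 = rng.binomial(2, 0.3, n).astype(float)
        geno = _geno_df(np.column_stack([g0, g0]))  # perfect LD
        pos = pd.Series([1_000, 2_001_000], index=geno.columns)  # 2 Mb apart
        out = clump(_records([1e-10, 1e-9]), geno, pos)
        assert len(out) == 2

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 21))
            n = 60
            G = rng.binomial(2, rng.uniform(0.1, 0.5, m), (n, m)).astype(float)
            # copy some columns to create LD
            for j in range(1, m):
                if rng.random() < 0.4:
                    G[:, j] = G[:, j - 1]
            G += 0.0
            keep = G.std(axis=0) > 0
            G = G[:, keep]
            m = G.shape[1]
            if m < 2:
                continue
            pvals = 10.0 ** (-rng.uniform(0, 12, m))
            positions = np.sort(rng.integers(1, 3_000_000, m))
            geno = _geno_df(G)
            pos = pd.Series(positions, index=geno.columns)
            got = clump(_records(pvals), geno, pos)
            expect = brute_force_clump(pvals, positions, G)
            got_set = [(c.lead_variant, frozenset(c.clump_members)) for c in got]
            exp_set = [(f"v{l}", frozenset(f"v{j}" for j in mem))
                       for l, mem in expect]
            assert sorted(got_set) == sorted(exp_set)


class TestClassifyCisTrans:
    def _tables(self):
        variants = pd.DataFrame({
            "chrom": ["1", "1", "1", "2"],
            "pos": [5_000_000, 6_000_000, 6_000_001, 5_000_000],
            "ref": "A", "alt": "G", "consequence": "intergenic",
            "gene_id": "", "aa_pos": np.nan,
        }, index=pd.Index(["at_tss", "edge", "past_edge", "other_chrom"],
                          name="variant_id"))
        genes = pd.DataFrame({"gene_id": ["G1"], "chrom": ["1"],
                              "tss": [5_000_000], "strand": ["+"]},
                             index=pd.Index(["PROT0"], name="protein_id"))
        return variants, genes

    @pytest.mark.parametrize("lead,cis,dist", [
        ("at_tss", True, 0),
        ("edge", True, 1_000_000),       # window inclusive at exactly 1 Mb
        ("past_edge", False, 1_000_001),
        ("other_chrom", False, None),
    ])
    def test_window_convention(self, lead, cis, dist):
        variants, genes = self._tables()
        rec = PqtlRecord("PROT0", lead, [lead], 1e-10, 0.5, 0.05)
        out = classify_cis_trans(rec, variants, genes)
        assert out.cis is cis
        assert out.tss_distance == dist

    def test_unmapped_protein_is_unknown(self):
        variants, genes = self._tables()
        rec = PqtlRecord("PROTX", "at_tss", ["at_tss"], 1e-10, 0.5, 0.05)
        out = classify_cis_trans(rec, variants, genes)
        assert out.cis is None


class TestConditionalScan:
    def _run(self, betas, seed, ld_copy=False):
        cfg = simdata.SimConfig(
            n_samples=1_500, n_variants=6, n_proteins=1,
            peptides_per_protein=(1, 1), maf_range=(0.3, 0.4),
            missing_intercept=-50.0, noise_sd_protein=1.0,
            covariate_betas={}, seed=seed)
        geno, variants = simdata.simulate_genotypes(cfg)
        if ld_copy:
            geno["rs1"] = geno["rs0"]
        cov = simdata.simulate_covariates(cfg)
        G = geno.to_numpy()
        rng = np.random.default_rng(seed)
        y = sum(b * G[:, j] for j, b in enumerate(betas)) \
            + rng.normal(0, 1, len(G))
        from plasmapqtl.io_formats import CohortBundle
        prot = pd.DataFrame({"PROT0": y}, index=geno.index)
        bundle = CohortBundle(
            genotypes=geno, variants=variants, proteins=prot,
            protein_genes=simdata._gene_layout(cfg),
            peptides=prot.rename(columns={"PROT0": "PROT0_pep1"}),
            peptide_map=pd.DataFrame(
                {"protein_id": ["PROT0"], "aa_start": [1], "aa_end": [9]},
                index=pd.Index(["PROT0_pep1"], name="peptide_id")),
            covariates=cov)
        lead = PqtlRecord("PROT0", "rs0", ["rs0"], 1e-20, 0.5, 0.05)
        return conditional_scan(bundle, y, [lead])

    def test_single_signal_gives_one_record(self):
        out = self._run([0.6, 0, 0, 0, 0, 0], seed=41)
        assert len(out) == 1
        assert out[0].lead_variant == "rs0"
        assert out[0].conditional_rank == 1

    def test_two_independent_signals_recovered(self):
        hits = 0
        for seed in range(42, 52):
            out = self._run([0.5, 0, 0.5, 0, 0, 0], seed=seed)
            leads = {o.lead_variant for o in out}
            hits += {"rs0", "rs2"} <= leads and len(out) == 2
        assert hits >= 9

    def test_perfectly_correlated_pair_yields_one_signal(self):
        out = self._run([0.5, 0.0, 0, 0, 0, 0], seed=60, ld_copy=True)
        assert len(out) == 1


class TestStudyWideThreshold:
    def test_published_values(self):
        t = study_wide_threshold(5e-8, 1216)
        assert float(f"{t:.1e}") == 4.1e-11
        assert study_wide_threshold(0.05, 20_000) == pytest.approx(2.5e-6)

    def test_single_protein_identity(self):
        assert study_wide_threshold(5e-8, 1) == 5e-8

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            study_wide_threshold(5e-8, 0)
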