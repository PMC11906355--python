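import dataclasses

import numpy as np
import pandas as pd
import pytest

from plasmapqtl import gwas, simdata
from plasmapqtl.simdata import ConfigurationError, PlantedEffect, SimConfig


def _clean_cfg(**kw):
    defaults = dict(n_samples=200, n_variants=20, n_proteins=3,
                    peptides_per_protein=(2, 3), missing_intercept=-50.0, seed=7)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGenotypes:
    def test_hwe_frequencies_at_maf_half(self):
        cfg = _clean_cfg(n_samples=10_000, maf_range=(0.5, 0.5))
        geno, _ = simdata.simulate_genotypes(cfg)
        counts = geno.iloc[:, 0].value_counts(normalize=True)
        assert counts[0.0] == pytest.approx(0.25, abs=0.02)
        assert counts[1.0] == pytest.approx(0.50, abs=0.02)
        assert counts[2.0] == pytest.approx(0.25, abs=0.02)

    def test_allele_frequency_matches_maf(self):
        # binomial sampling: SE of the AF estimate at n=10,000 is ~0.0032
        cfg = _clean_cfg(n_samples=10_000, maf_range=(0.3, 0.3))
        geno, _ = simdata.simulate_genotypes(cfg)
        af = geno.to_numpy().mean(axis=0) / 2.0
        assert np.all(np.abs(af - 0.3) < 0.01)

    def test_full_ld_copies_columns(self):
        cfg = _clean_cfg(ld_decay=1.0)
        geno, _ = simdata.simulate_genotypes(cfg)
        first = geno.iloc[:, 0]
        for col in geno.columns[1:]:
            assert (geno[col] == first).all()

    def test_hwe_holds_without_ld(self):
        cfg = _clean_cfg(n_samples=2_000, n_variants=500, ld_decay=0.0)
        geno, _ = simdata.simulate_genotypes(cfg)
        pvals = [gwas.hwe_pvalue(int((c == 0).sum()), int((c == 1).sum()),
                                 int((c == 2).sum()))
                 for _, c in geno.items()]
        assert np.mean(np.asarray(pvals) > 1e-6) >= 0.999

    def test_invalid_maf_rejected(self):
        with pytest.raises(ConfigurationError, match="MAF"):
            simdata.simulate_genotypes(_clean_cfg(maf_range=(0.0, 0.5)))
        with pytest.raises(ConfigurationError, match="MAF"):
            simdata.simulate_genotypes(_clean_cfg(maf_range=(0.1, 0.6)))


class TestPlantedEffects:
    def test_artefact_requires_peptide_and_position(self):
        with pytest.raises(ConfigurationError, match="artefact"):
            PlantedEffect(variant_index=0, protein_index=0, beta=0.0,
                          kind="artefact")

    def test_artefact_protein_beta_must_be_zero(self):
        with pytest.raises(ConfigurationError, match="peptide-only"):
            PlantedEffect(variant_index=0, protein_index=0, beta=0.5,
                          kind="artefact", artefact_peptide_index=0,
                          aa_position=10)

    def test_out_of_range_indices_rejected(self):
        eff = PlantedEffect(variant_index=99, protein_index=0, beta=0.5)
        with pytest.raises(ConfigurationError, match="out of range"):
            simdata.simulate_genotypes(_clean_cfg(planted_effects=[eff]))


class TestProteome:
    def test_noiseless_cis_effect_is_exact(self):
        eff = [PlantedEffect(variant_index=2, protein_index=0, beta=1.0)]
        cfg = _clean_cfg(n_samples=500, noise_sd_protein=0.0,
                         noise_sd_peptide=0.0, planted_effects=eff,
                         covariate_betas={})
        bundle = simdata.simulate_cohort(cfg)
        g = bundle.genotypes["rs2"]
        y = bundle.proteins["PROT0"]
        diff = y[g == 2].mean() - y[g == 0].mean()
        assert diff == pytest.approx(2.0, abs=1e-12)

    def test_artefact_peptide_missing_at_hom_alt_siblings_unaffected(self):
        eff = [PlantedEffect(variant_index=0, protein_index=0, beta=0.0,
                             kind="artefact", artefact_peptide_index=0,
                             aa_position=25)]
        cfg = _clean_cfg(n_samples=600, maf_range=(0.4, 0.5),
                         planted_effects=eff)
        bundle = simdata.simulate_cohort(cfg)
        g = bundle.genotypes["rs0"]
        pep_ids = bundle.peptide_map.index[
            bundle.peptide_map["protein_id"] == "PROT0"]
        artefact, siblings = pep_ids[0], pep_ids[1:]
        hom = g == 2
        assert hom.any()
        assert bundle.peptides.loc[hom, artefact].isna().all()
        assert bundle.peptides.loc[hom, siblings].notna().to_numpy().mean() > 0.9
        # artefact peptide spans the planted residue
        row = bundle.peptide_map.loc[artefact]
        assert row["aa_start"] <= 25 <= row["aa_end"]

    def test_heterozygote_loses_one_log2_unit_on_artefact_peptide(self):
        eff = [PlantedEffect(variant_index=0, protein_index=0, beta=0.0,
                             kind="artefact", artefact_peptide_index=0,
                             aa_position=25)]
        cfg = _clean_cfg(n_samples=2_000, maf_range=(0.3, 0.3),
                         noise_sd_protein=0.0, noise_sd_peptide=0.0,
                         planted_effects=eff, covariate_betas={})
        bundle = simdata.simulate_cohort(cfg)
        g = bundle.genotypes["rs0"]
        pep = bundle.peptide_map.index[
            bundle.peptide_map["protein_id"] == "PROT0"][0]
        y = bundle.peptides[pep]
        assert (y[g == 1].mean() - y[g == 0].mean()) == pytest.approx(-1.0, abs=1e-9)

    def test_mnar_missingness_targets_low_abundance(self):
        cfg = _clean_cfg(n_samples=400, n_proteins=30, baseline_sd=3.0,
                         missing_intercept=-2.0, missing_slope=-1.0)
        bundle = simdata.simulate_cohort(cfg)
        base = bundle.proteins.mean()
        miss = bundle.proteins.isna().mean()
        low = miss[base < base.median()].mean()
        high = miss[base >= base.median()].mean()
        assert low > high

    def test_ols_recovers_planted_beta(self):
        hits = 0
        for seed in range(30):
            eff = [PlantedEffect(variant_index=0, protein_index=0, beta=0.5)]
            cfg = _clean_cfg(n_samples=1_000, maf_range=(0.3, 0.3),
                             noise_sd_protein=1.0, planted_effects=eff,
                             covariate_betas={}, seed=seed)
            geno, _ = simdata.simulate_genotypes(cfg)
            cov = simdata.simulate_covariates(cfg)
            prot, _, _ = simdata.simulate_proteome(cfg, geno, cov)
            beta, se, _ = gwas.assoc_scan_matrix(
                geno.to_numpy()[:, :1], prot["PROT0"].to_numpy())
            hits += abs(beta[0] - 0.5) < 3 * se[0]
        assert hits >= 29


class TestReproducibility:
    def test_same_seed_bitwise_identical(self):
        cfg = _clean_cfg(missing_intercept=-2.0)
        a = simdata.simulate_cohort(cfg)
        b = simdata.simulate_cohort(dataclasses.replace(cfg))
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.proteins, b.proteins)
        pd.testing.assert_frame_equal(a.peptides, b.peptides)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)

    def test_different_seeds_differ(self):
        a = simdata.simulate_cohort(_clean_cfg(seed=1))
        b = simdata.simulate_cohort(_clean_cfg(seed=2))
        assert not a.proteins.equals(b.proteins)


class TestOutcomeGwas:
    def test_nonfinite_theta_rejected(self):
        with pytest.raises(ConfigurationError, match="theta"):
            simdata.simulate_outcome_gwas(_clean_cfg(), theta=np.inf)

    def test_null_theta_centers_outcome_beta(self):
        eff = [PlantedEffect(variant_index=0, protein_index=0, beta=0.8)]
        cfg = _clean_cfg(n_samples=1_500, planted_effects=eff)
        stats = simdata.simulate_outcome_gwas(cfg, theta=0.0)
        row = stats[stats["variant_id"] == "rs0"].iloc[0]
        assert abs(row["beta"] / row["se"]) < 4.0

    def test_noiseless_identity_trait_reproduces_exposure_beta(self):
        eff = [PlantedEffect(variant_index=0, protein_index=0, beta=0.8)]
        cfg = _clean_cfg(n_samples=800, noise_sd_protein=0.0,
                         planted_effects=eff, covariate_betas={})
        stats = simdata.simulate_outcome_gwas(cfg, theta=1.0, noise_sd=0.0)
        row = stats[stats["variant_id"] == "rs0"].iloc[0]
        # trait == protein, so the per-variant outcome beta is the planted one
        assert row["beta"] == pytest.approx(0.8, abs=1e-10)

    def test_wald_ratio_recovers_theta(self):
        eff = [PlantedEffect(variant_index=0, protein_index=0, beta=0.8)]
        cfg = _clean_cfg(n_samples=4_000, maf_range=(0.3, 0.3),
                         noise_sd_protein=0.3, planted_effects=eff,
                         covariate_betas={})
        outcome = simdata.simulate_outcome_gwas(cfg, theta=0.4, noise_sd=0.2)
        # exposure betas measured in an independent draw of the same model
        cfg_exp = dataclasses.replace(cfg, seed=cfg.seed + 999)
        geno, _ = simdata.simulate_genotypes(cfg_exp)
        cov = simdata.simulate_covariates(cfg_exp)
        prot, _, _ = simdata.simulate_proteome(cfg_exp, geno, cov)
        b_exp, se_exp, _ = gwas.assoc_scan_matrix(
            geno.to_numpy()[:, :1], prot["PROT0"].to_numpy())
        row = outcome[outcome["variant_id"] == "rs0"].iloc[0]
        wald = row["beta"] / b_exp[0]
        wald_se = row["se"] / abs(b_exp[0])
        assert abs(wald - 0.4) < 3 * wald_se + 3 * se_exp[0]
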