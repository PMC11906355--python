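"""End-to-end orchestration: simulate → preprocess → associate → map pQTLs
→ tier → decompose → predict → MR/coloc → replicate.

Every stage writes a TSV artifact whose first line is a comment header
embedding the configuration hash, and the run ends with a machine-readable
JSON manifest (seed, thresholds, stage row counts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import causal, gwas, pheno_assoc, pqtl, predict, preprocess, replication
from . import simdata, tiers, varexp
from .io_formats import CohortBundle

__all__ = ["PipelineConfig", "run_pipeline", "demo_config", "preprocess_bundle"]


@dataclasses.dataclass
class PipelineConfig:
    """All thresholds of the pipeline, with the published defaults."""

    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    var_call: float = 0.95
    sample_call: float = 0.95
    het_sd: float = 3.0
    min_valid_fraction: float = 0.6
    impute_shift: float = 1.8
    impute_width: float = 0.3
    gw_p: float = 5e-8
    peptide_alpha: float = 2.4e-5
    ld_r2_min: float = 0.2
    window_bp: int = 1_000_000
    mr_alpha: float = 2.5e-6
    coloc_pp4_min: float = 0.7
    replication_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name != "seed" and not v > 0:
                raise ValueError(f"threshold {f.name} must be positive, got {v}")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _log(msg: str) -> None:
    print(f"[{time.strftime('%Y-%m-%dT%H:%M:%S')}] {msg}", file=sys.stderr)


def _write(path: Path, df: pd.DataFrame, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# plasmapqtl config_hash={config.digest()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", na_rep="")


def demo_config(seed: int = 0, n_samples: int = 500) -> simdata.SimConfig:
    """The demo cohort: planted cis, trans and artefact effects."""
    rng = np.random.default_rng(seed)
    n_proteins = 40
    n_variants = 300
    effects = []
    # 8 strong cis effects with heterogeneous signed betas, 2 trans,
    # 2 variant-spanning artefacts
    for i, p in enumerate(range(0, 16, 2)):
        beta = (-1) ** i * (0.45 + 0.06 * i)
        effects.append(simdata.PlantedEffect(
            variant_index=i, protein_index=p, beta=beta, kind="cis"))
    for i, p, beta in zip((20, 21), (20, 22), (0.5, -0.65)):
        effects.append(simdata.PlantedEffect(
            variant_index=i, protein_index=p, beta=beta, kind="trans"))
    for i, p in zip((30, 31), (30, 32)):
        effects.append(simdata.PlantedEffect(
            variant_index=i, protein_index=p, beta=0.0, kind="artefact",
            artefact_peptide_index=0, aa_position=25))
    betas_age = np.zeros(n_proteins)
    betas_age[[1, 3, 5]] = 0.05       # log2 units per year
    betas_sex = np.zeros(n_proteins)
    betas_sex[[7, 9]] = 0.4
    betas_bmi = np.zeros(n_proteins)
    betas_bmi[[11, 13]] = 0.2
    return simdata.SimConfig(
        n_samples=n_samples, n_variants=n_variants, n_proteins=n_proteins,
        planted_effects=effects,
        covariate_betas={"age": betas_age, "sex": betas_sex, "bmi_sds": betas_bmi},
        ld_decay=0.2, seed=seed,
    )


def preprocess_bundle(bundle: CohortBundle, config: PipelineConfig):
    """Shared proteomics preprocessing for one cohort.

    Returns ``(protein_phenotypes, peptide_phenotypes, imputed_log2)``:
    residualized re-INT protein and peptide matrices for association, plus
    the filtered+imputed log2 protein matrix (for fold changes, prediction).
    """
    prot, _ = preprocess.filter_completeness(bundle.proteins,
                                             config.min_valid_fraction)
    prot = preprocess.impute_downshifted(prot, shift=config.impute_shift,
                                         width=config.impute_width,
                                         seed=config.seed + 1)
    pep, _ = preprocess.filter_completeness(bundle.peptides,
                                            config.min_valid_fraction)
    pep = preprocess.impute_downshifted(pep, shift=config.impute_shift,
                                        width=config.impute_width,
                                        seed=config.seed + 2)
    prot_ph = preprocess.residualize(prot, bundle.covariates)
    pep_ph = preprocess.residualize(pep, bundle.covariates)
    return prot_ph, pep_ph, prot


def run_pipeline(bundle: CohortBundle, outdir: str | Path,
                 config: PipelineConfig | None = None,
                 replication_bundle: CohortBundle | None = None,
                 outcome_stats: pd.DataFrame | None = None) -> dict:
    """Run every analysis stage on a cohort bundle; write artifacts to outdir.

    Returns the run manifest (also written as ``manifest.json``).
    """
    config = config or PipelineConfig()
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config),
                      "config_hash": config.digest(), "stages": {}}

    _log("stage qc: genotype quality control")
    bundle, qc_report = gwas.qc_genotypes(
        bundle, maf_min=config.maf_min, hwe_p_min=config.hwe_p_min,
        var_call=config.var_call, sample_call=config.sample_call,
        het_sd=config.het_sd)
    manifest["stages"]["qc"] = dataclasses.asdict(qc_report)

    _log("stage preprocess: filter, impute, INT, residualize")
    prot_ph, pep_ph, prot_imputed = preprocess_bundle(bundle, config)
    manifest["stages"]["preprocess"] = {
        "n_proteins": prot_ph.shape[1], "n_peptides": pep_ph.shape[1]}

    _log("stage pheno-assoc: demographic associations")
    prot_int = preprocess.int_matrix(prot_imputed)
    bundle_int = dataclasses.replace(bundle, proteins=prot_int)
    assoc = pheno_assoc.fit_pheno_model(bundle_int)
    _write(outdir / "pheno_assoc.tsv", assoc, config)
    vif, norm = pheno_assoc.diagnostics(bundle_int)
    _write(outdir / "diagnostics_vif.tsv", vif, config)
    manifest["stages"]["pheno_assoc"] = {
        "n_significant": int(assoc["significant"].sum()),
        "fraction_residuals_normal": norm.attrs["fraction_normal"],
        "max_vif": float(vif["vif"].replace(np.inf, np.nan).max()),
    }

    _log("stage pqtl-map: association scan + clumping")
    study_p = pqtl.study_wide_threshold(config.gw_p, prot_ph.shape[1])
    pqtls = pqtl.discover_pqtls(bundle, prot_ph, p_max=config.gw_p,
                                r2_min=config.ld_r2_min,
                                window_bp=config.window_bp,
                                study_wide_p=study_p)
    lambdas = []
    for pid in prot_ph.columns:
        recs = gwas.assoc_scan(bundle, prot_ph[pid].to_numpy(), pid)
        lambdas.append(gwas.lambda_gc([r.p for r in recs if not r.failed]))
    pqtl_df = pd.DataFrame([
        {"protein_id": q.protein_id, "lead_variant": q.lead_variant,
         "p_lead": q.p_lead, "beta_lead": q.beta_lead, "se_lead": q.se_lead,
         "cis": q.cis, "tss_distance": q.tss_distance,
         "significance": q.significance,
         "clump_members": ";".join(q.clump_members)}
        for q in pqtls])
    _write(outdir / "pqtls.tsv", pqtl_df, config)
    cis_flags = [q.cis for q in pqtls if q.cis is not None]
    manifest["stages"]["pqtl_map"] = {
        "n_primary_pqtls": len(pqtls),
        "n_proteins_with_pqtl": int(pqtl_df["protein_id"].nunique()) if len(pqtl_df) else 0,
        "fraction_cis": float(np.mean(cis_flags)) if cis_flags else np.nan,
        "study_wide_threshold": study_p,
        "median_lambda_gc": float(np.median(lambdas)) if lambdas else np.nan,
    }

    _log("stage tier: peptide-level validation")
    tier_records = tiers.tier_pqtls(bundle, pqtls, pep_ph,
                                    alpha_pep=config.peptide_alpha)
    tier_df = pd.DataFrame([
        {"variant_id": t.variant_id, "protein_id": t.protein_id,
         "n_peptides_total": t.n_peptides_total,
         "n_peptides_significant": t.n_peptides_significant,
         "consequence": t.consequence, "in_coding_gene": t.in_coding_gene,
         "spanning": t.spanning, "tier": t.tier, "reason": t.reason}
        for t in tier_records])
    _write(outdir / "tiers.tsv", tier_df, config)
    manifest["stages"]["tier"] = {
        "by_tier": tier_df["tier"].value_counts().to_dict() if len(tier_df) else {}}
    try:
        manifest["stages"]["tier"]["concordance"] = tiers.concordance_summary(tier_records)
    except ValueError:
        manifest["stages"]["tier"]["concordance"] = None

    _log("stage varexp: conditional signals + variance decomposition")
    leads_by_protein: dict[str, list[str]] = {}
    for pid in prot_ph.columns:
        mine = [q for q in pqtls if q.protein_id == pid]
        if not mine:
            continue
        cond = pqtl.conditional_scan(bundle, prot_ph[pid].to_numpy(), mine,
                                     p_max=config.gw_p,
                                     window_bp=config.window_bp)
        leads_by_protein[pid] = [c.lead_variant for c in cond]
    decomps = []
    for pid, leads in leads_by_protein.items():
        d = varexp.decompose_variance(bundle, pid, leads,
                                      phenotype=prot_int[pid].to_numpy())
        decomps.append({"protein_id": pid, **d.fractions, "total_r2": d.total_r2})
    decomp_df = pd.DataFrame(decomps)
    _write(outdir / "variance_decomposition.tsv", decomp_df, config)
    manifest["stages"]["varexp"] = {
        "n_conditional_signals": int(sum(len(v) for v in leads_by_protein.values())),
        "mean_pqtl_fraction": float(decomp_df["pqtls"].mean()) if len(decomp_df) else np.nan,
    }

    _log("stage effect-size: allelic fold changes")
    raw = (2.0 ** prot_imputed)
    afc_rows = []
    for q in pqtls:
        if q.protein_id not in raw.columns:
            continue
        es = varexp.allelic_fold_change(raw[q.protein_id],
                                        bundle.genotypes[q.lead_variant],
                                        q.lead_variant, q.protein_id)
        afc_rows.append(dataclasses.asdict(es))
    afc_df = pd.DataFrame(afc_rows)
    _write(outdir / "effect_sizes.tsv", afc_df, config)

    _log("stage predict: age and BMI-SDS from proteins")
    pred_reports = {}
    for outcome in ("age", "bmi_sds"):
        rep = predict.train_predictor(prot_imputed, bundle.covariates[outcome],
                                      outcome_name=outcome,
                                      k_max=min(200, prot_imputed.shape[1]),
                                      seed=config.seed)
        pred_reports[outcome] = {"k_selected": rep.k_selected,
                                 "test_mae": rep.test_mae, "test_r": rep.test_r}
    manifest["stages"]["predict"] = pred_reports

    if outcome_stats is not None:
        _log("stage mr/coloc: causal integration")
        cis_pqtls = [q for q in pqtls if q.cis]
        exp_rows = []
        for q in cis_pqtls:
            v = bundle.variants.loc[q.lead_variant]
            exp_rows.append({
                "variant_id": q.lead_variant, "chrom": v["chrom"], "pos": v["pos"],
                "effect_allele": v["alt"], "other_allele": v["ref"],
                "eaf": float(bundle.genotypes[q.lead_variant].mean() / 2.0),
                "beta": q.beta_lead, "se": q.se_lead, "pval": q.p_lead,
                "n": bundle.n_samples, "protein_id": q.protein_id,
            })
        exposure = pd.DataFrame(exp_rows)
        mr_rows = []
        for _, row in exposure.iterrows():
            try:
                res = causal.wald_ratio(exposure, outcome_stats,
                                        row["variant_id"],
                                        protein_id=row["protein_id"],
                                        trait_id="trait",
                                        alpha_mr=config.mr_alpha)
            except (causal.HarmonizationError, ValueError, KeyError):
                continue
            mr_rows.append({"protein_id": res.protein_id,
                            "instrument": res.instrument,
                            "wald_beta": res.wald_beta, "wald_se": res.wald_se,
                            "wald_p": res.wald_p,
                            "mr_significant": res.mr_significant})
        mr_df = pd.DataFrame(mr_rows)
        _write(outdir / "mendelian_randomization.tsv", mr_df, config)
        manifest["stages"]["mr"] = {
            "n_tested": len(mr_df),
            "n_significant": int(mr_df["mr_significant"].sum()) if len(mr_df) else 0}

    if replication_bundle is not None:
        _log("stage replicate: independent cohort")
        rep_bundle, _ = gwas.qc_genotypes(
            replication_bundle, maf_min=config.maf_min,
            hwe_p_min=config.hwe_p_min, var_call=config.var_call,
            sample_call=config.sample_call, het_sd=config.het_sd)
        rep_ph, _, _ = preprocess_bundle(rep_bundle, config)
        rep_records = replication.replicate(pqtls, rep_bundle, rep_ph,
                                            alpha=config.replication_alpha)
        summary = replication.replication_summary(rep_records)
        rep_df = pd.DataFrame([dataclasses.asdict(r) for r in rep_records])
        _write(outdir / "replication.tsv", rep_df, config)
        manifest["stages"]["replicate"] = summary

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    _log(f"pipeline complete; manifest at {manifest_path}")
    return manifest


def run_demo(outdir: str | Path, seed: int = 0, n_samples: int = 500) -> dict:
    """Simulate a discovery + replication cohort and run the full pipeline."""
    sim = demo_config(seed=seed, n_samples=n_samples)
    bundle = simdata.simulate_cohort(sim)
    rep_sim = dataclasses.replace(sim, seed=seed + 50_021)
    rep_bundle = simdata.simulate_cohort(rep_sim)
    outcome = simdata.simulate_outcome_gwas(sim, theta=0.3)
    config = PipelineConfig(seed=seed)
    return run_pipeline(bundle, outdir, config=config,
                        replication_bundle=rep_bundle, outcome_stats=outcome)
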