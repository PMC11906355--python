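"""Synthetic pediatric-cohort generator.

Emulates the statistical structure the analysis assumes: Hardy–Weinberg
genotypes with optional first-order LD, plasma protein log2 intensities
driven by planted cis/trans genetic effects and demographic covariates,
peptide intensities derived from their parent proteins, variant-spanning
peptides whose detectability depends on alternate-allele dosage, and
abundance-dependent (missing-not-at-random) dropout.

The generator's defaults follow the cohort this pipeline was designed
around: ~children aged 5–20 years, roughly half recruited from an obesity
clinic, BMI-SDS near 0 in the general-population arm and ~2.8 (s.d. 0.75)
in the obesity arm, plasma stored 0–10 years before measurement.

The artefact mechanism: a bottom-up proteomics search against the reference
sequence database cannot detect a peptide carrying a substituted amino
acid, so for a peptide spanning a protein-altering variant only the
reference version is quantified.  Its linear-scale intensity is attenuated
by ``(2 − dosage) / 2`` — heterozygotes retain half the reference peptide,
alternate homozygotes none — which creates a dose-dependent peptide-level
association with no true change in protein abundance.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import CohortBundle

__all__ = [
    "SimConfig",
    "PlantedEffect",
    "ConfigurationError",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_proteome",
    "simulate_cohort",
    "simulate_outcome_gwas",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclasses.dataclass(frozen=True)
class PlantedEffect:
    """A genetic effect planted in the synthetic proteome.

    ``beta`` is the protein-level effect per alternate-allele dosage on the
    log2 scale.  ``kind`` is ``cis`` (variant placed within the cis window
    of the protein's gene), ``trans`` (placed far from it), or ``artefact``:
    a protein-altering variant whose only footprint is allele-dependent
    detectability of the peptide spanning the encoded substitution — the
    protein-level beta must then be 0.
    """

    variant_index: int
    protein_index: int
    beta: float
    kind: str = "cis"
    artefact_peptide_index: int | None = None
    aa_position: int | None = None

    def __post_init__(self):
        if self.kind not in ("cis", "trans", "artefact"):
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        if self.kind == "artefact":
            if self.artefact_peptide_index is None or self.aa_position is None:
                raise ConfigurationError(
                    "artefact effects require artefact_peptide_index and aa_position"
                )
            if self.beta != 0.0:
                raise ConfigurationError(
                    "artefact effects are peptide-only: protein-level beta must be 0"
                )


@dataclasses.dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    Parameters
    ----------
    n_samples, n_variants, n_proteins : int
        Cohort dimensions.
    peptides_per_protein : (int, int)
        Inclusive range; the per-protein count is drawn uniformly.
    maf_range : (float, float)
        Minor-allele frequencies drawn uniformly from this range, in (0, 0.5].
    ld_decay : float
        Probability, per sample and adjacent variant pair, that the genotype
        is copied from the previous variant (first-order copy-chain LD);
        1.0 makes adjacent variants identical, 0.0 independent.
    planted_effects : list of PlantedEffect
    covariate_betas : dict
        Per-covariate arrays of length n_proteins with log2-scale effects of
        age (per year), sex (female vs male), BMI-SDS (per unit), obesity,
        and storage (per year) on each protein; missing keys mean no effect.
    obese_fraction : float
        Fraction recruited from the obesity clinic.
    missing_intercept, missing_slope : float
        MNAR logistic dropout: P(missing) = expit(intercept + slope * log2
        intensity centred at the cohort mean); a negative slope makes
        low-abundance features drop out more often.
    noise_sd_protein, noise_sd_peptide : float
        log2-scale residual standard deviations.
    baseline_mean, baseline_sd : float
        log2 baseline abundance distribution across proteins.
    """

    n_samples: int = 500
    n_variants: int = 200
    n_proteins: int = 50
    peptides_per_protein: tuple[int, int] = (3, 8)
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.0
    planted_effects: list[PlantedEffect] = dataclasses.field(default_factory=list)
    covariate_betas: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    obese_fraction: float = 0.55
    missing_intercept: float = -20.0
    missing_slope: float = -1.5
    noise_sd_protein: float = 0.5
    noise_sd_peptide: float = 0.3
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    variant_spacing: int = 5_000
    gene_spacing: int = 3_000_000
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"MAFs must lie in (0, 0.5], got {self.maf_range}")
        if self.noise_sd_protein < 0 or self.noise_sd_peptide < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        if not (0.0 <= self.ld_decay <= 1.0):
            raise ConfigurationError("ld_decay must be a probability in [0, 1]")
        if not (0.0 <= self.obese_fraction <= 1.0):
            raise ConfigurationError("obese_fraction must be in [0, 1]")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ConfigurationError("peptides_per_protein range must be >= 1")
        for eff in self.planted_effects:
            if not (0 <= eff.variant_index < self.n_variants):
                raise ConfigurationError(f"variant index {eff.variant_index} out of range")
            if not (0 <= eff.protein_index < self.n_proteins):
                raise ConfigurationError(f"protein index {eff.protein_index} out of range")


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Named substream of the config's root seed (stage-level reproducibility)."""
    # str hash is salted per interpreter run; crc32 is stable
    key = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


def _gene_layout(config: SimConfig) -> pd.DataFrame:
    """One gene per protein, spaced gene_spacing apart on chromosome 1."""
    tss = (np.arange(config.n_proteins) + 1) * config.gene_spacing
    return pd.DataFrame(
        {
            "gene_id": [f"GENE{i}" for i in range(config.n_proteins)],
            "chrom": "1",
            "tss": tss,
            "strand": "+",
        },
        index=pd.Index([f"PROT{i}" for i in range(config.n_proteins)],
                       name="protein_id"),
    )


def simulate_genotypes(config: SimConfig):
    """Draw the dosage matrix and variant table.

    Each variant is drawn under Hardy–Weinberg equilibrium at its MAF
    (dosage ~ Binomial(2, maf)); with probability ``ld_decay`` a sample's
    genotype at variant *j* is instead copied from variant *j − 1*, giving
    a first-order LD block structure.  Variant positions: cis effects are
    placed 10 kb from their protein's TSS, trans effects on chromosome 2,
    all remaining variants tile chromosome 1 every ``variant_spacing`` bp.

    Returns
    -------
    (genotypes, variants) : (DataFrame samples x variants, DataFrame)
    """
    config.validate()
    rng = _rng(config, "genotypes")
    n, m = config.n_samples, config.n_variants
    mafs = rng.uniform(*config.maf_range, size=m)

    fresh = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)
    if config.ld_decay > 0 and m > 1:
        copy = rng.random(size=(n, m)) < config.ld_decay
        copy[:, 0] = False
        geno = fresh.copy()
        for j in range(1, m):
            geno[:, j] = np.where(copy[:, j], geno[:, j - 1], fresh[:, j])
    else:
        geno = fresh

    genes = _gene_layout(config)
    chrom = np.full(m, "1", dtype=object)
    pos = (np.arange(m) + 1) * config.variant_spacing
    consequence = np.full(m, "intergenic", dtype=object)
    gene_id = np.full(m, "", dtype=object)
    aa_pos = np.full(m, np.nan)
    bases = np.array(["A", "C", "G", "T"])
    ref = bases[rng.integers(0, 4, size=m)]
    alt = np.array([bases[(list(bases).index(r) + 1) % 4] for r in ref])

    for eff in config.planted_effects:
        j, p = eff.variant_index, eff.protein_index
        g = genes.iloc[p]
        if eff.kind == "cis":
            chrom[j], pos[j] = g["chrom"], int(g["tss"]) + 10_000
            gene_id[j] = g["gene_id"]
        elif eff.kind == "trans":
            chrom[j], pos[j] = "2", (j + 1) * config.variant_spacing
        else:  # artefact: missense inside the protein-coding gene
            chrom[j], pos[j] = g["chrom"], int(g["tss"]) + 1_000
            gene_id[j] = g["gene_id"]
            consequence[j] = "missense"
            aa_pos[j] = eff.aa_position

    ids = [f"rs{j}" for j in range(m)]
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
         "consequence": consequence, "gene_id": gene_id, "aa_pos": aa_pos},
        index=pd.Index(ids, name="variant_id"),
    )
    genotypes = pd.DataFrame(geno, columns=ids,
                             index=pd.Index([f"S{i}" for i in range(n)],
                                            name="sample_id"))
    return genotypes, variants


def simulate_covariates(config: SimConfig) -> pd.DataFrame:
    """Demographic covariates: age ~ U(5, 20) years, sex ~ Bernoulli(0.5)
    (female = 1), BMI-SDS ~ N(0, 0.81) for the general-population arm and
    N(2.8, 0.75²) for the obesity-clinic arm, puberty a logistic function of
    age, storage ~ U(0, 10) years, and a standard-normal PC1 placeholder."""
    rng = _rng(config, "covariates")
    n = config.n_samples
    age = rng.uniform(5.0, 20.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    obesity = (rng.random(n) < config.obese_fraction).astype(float)
    bmi_sds = np.where(obesity == 1,
                       rng.normal(2.8, 0.75, size=n),
                       rng.normal(0.0, 0.81, size=n))
    # puberty onset around 11 y; logistic in age with scale 1 y
    puberty = (rng.random(n) < expit(age - 11.0)).astype(float)
    storage = rng.uniform(0.0, 10.0, size=n)
    pc1 = rng.normal(0.0, 1.0, size=n)
    return pd.DataFrame(
        {"age": age, "sex": sex, "bmi_sds": bmi_sds, "obesity": obesity,
         "puberty": puberty, "storage": storage, "pc1": pc1},
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
    )


def simulate_proteome(config: SimConfig, genotypes: pd.DataFrame,
                      covariates: pd.DataFrame):
    """Generate protein and peptide log2 matrices plus the peptide map.

    log2 protein = baseline + Σ planted beta·dosage + covariate terms +
    N(0, noise_sd_protein).  log2 peptide = parent protein + fixed offset +
    N(0, noise_sd_peptide); artefact peptides are additionally attenuated by
    (2 − dosage)/2 on the linear scale (alternate homozygotes fully
    undetected).  MNAR dropout then blanks cells with probability
    expit(missing_intercept + missing_slope · centred log2 intensity).
    """
    config.validate()
    rng = _rng(config, "proteome")
    n, p = config.n_samples, config.n_proteins
    if genotypes.shape[0] != n or covariates.shape[0] != n:
        raise ConfigurationError("genotype/covariate dimensions inconsistent with config")

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=p)
    prot = np.tile(baseline, (n, 1))

    cov_terms = {"age": "age", "sex": "sex", "bmi_sds": "bmi_sds",
                 "obesity": "obesity", "storage": "storage"}
    for key, col in cov_terms.items():
        betas = config.covariate_betas.get(key)
        if betas is not None:
            betas = np.asarray(betas, dtype=float)
            if betas.shape != (p,):
                raise ConfigurationError(f"covariate_betas[{key!r}] must have length {p}")
            prot += covariates[col].to_numpy()[:, None] * betas[None, :]

    G = genotypes.to_numpy(dtype=float)
    for eff in config.planted_effects:
        if eff.kind != "artefact":
            prot[:, eff.protein_index] += eff.beta * G[:, eff.variant_index]
    prot += rng.normal(0.0, config.noise_sd_protein, size=(n, p))

    lo, hi = config.peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, size=p)
    pep_protein = np.repeat(np.arange(p), n_pep)
    total_pep = int(n_pep.sum())
    offsets = rng.normal(-1.0, 1.0, size=total_pep)
    pep = prot[:, pep_protein] + offsets[None, :] \
        + rng.normal(0.0, config.noise_sd_peptide, size=(n, total_pep))

    # peptide coordinates: non-overlapping 10-residue tryptic windows
    starts = np.concatenate([10 + 15 * np.arange(k) for k in n_pep]).astype(int)
    ends = starts + 9
    pep_ids = []
    counter: dict[int, int] = {}
    for pi in pep_protein:
        counter[pi] = counter.get(pi, 0) + 1
        pep_ids.append(f"PROT{pi}_pep{counter[pi]}")
    peptide_map = pd.DataFrame(
        {"protein_id": [f"PROT{pi}" for pi in pep_protein],
         "aa_start": starts, "aa_end": ends},
        index=pd.Index(pep_ids, name="peptide_id"),
    )

    # artefact peptides: reposition to span the substituted residue and
    # attenuate by the reference-allele fraction
    pep_index_of = {}
    for pi in range(p):
        pep_index_of[pi] = np.flatnonzero(pep_protein == pi)
    for eff in config.planted_effects:
        if eff.kind != "artefact":
            continue
        cols = pep_index_of[eff.protein_index]
        if eff.artefact_peptide_index >= len(cols):
            raise ConfigurationError(
                f"artefact_peptide_index {eff.artefact_peptide_index} out of range "
                f"for protein {eff.protein_index} with {len(cols)} peptides"
            )
        col = cols[eff.artefact_peptide_index]
        peptide_map.iloc[col, peptide_map.columns.get_loc("aa_start")] = eff.aa_position - 4
        peptide_map.iloc[col, peptide_map.columns.get_loc("aa_end")] = eff.aa_position + 5
        frac = (2.0 - G[:, eff.variant_index]) / 2.0
        with np.errstate(divide="ignore"):
            pep[:, col] += np.log2(frac)  # -inf at dosage 2 -> undetected

    pep[~np.isfinite(pep)] = np.nan

    prot_df = pd.DataFrame(prot, index=covariates.index,
                           columns=[f"PROT{i}" for i in range(p)])
    pep_df = pd.DataFrame(pep, index=covariates.index, columns=pep_ids)

    # MNAR dropout, centred on each matrix's own mean intensity
    for df, stream in ((prot_df, "miss_prot"), (pep_df, "miss_pep")):
        vals = df.to_numpy()
        centred = vals - np.nanmean(vals)
        p_miss = expit(config.missing_intercept + config.missing_slope * centred)
        drop = _rng(config, stream).random(vals.shape) < p_miss
        vals[drop] = np.nan
        df.iloc[:, :] = vals

    return prot_df, pep_df, peptide_map


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Generate a complete, sample-aligned cohort bundle."""
    genotypes, variants = simulate_genotypes(config)
    covariates = simulate_covariates(config)
    proteins, peptides, peptide_map = simulate_proteome(config, genotypes, covariates)
    return CohortBundle(
        genotypes=genotypes, variants=variants, proteins=proteins,
        protein_genes=_gene_layout(config), peptides=peptides,
        peptide_map=peptide_map, covariates=covariates,
    )


def simulate_outcome_gwas(config: SimConfig, theta: float,
                          noise_sd: float = 1.0) -> pd.DataFrame:
    """Simulate an external-trait GWAS in a fresh sample (two-sample design).

    A second cohort is drawn from the same genetic model; the trait is
    ``theta · protein + N(0, noise_sd)`` summed over proteins carrying
    planted effects, and per-variant beta/SE/P come from simple OLS of the
    trait on dosage.  Returns a summary-statistics table in the exchange
    schema.
    """
    if not np.isfinite(theta):
        raise ConfigurationError("theta must be finite")
    config.validate()
    cfg2 = dataclasses.replace(config, seed=config.seed + 10_007,
                               missing_intercept=-50.0)  # no dropout in the outcome cohort
    genotypes, variants = simulate_genotypes(cfg2)
    covariates = simulate_covariates(cfg2)
    proteins, _, _ = simulate_proteome(cfg2, genotypes, covariates)

    affected = sorted({e.protein_index for e in config.planted_effects
                       if e.kind != "artefact"})
    if affected:
        exposure = proteins.iloc[:, affected].sum(axis=1).to_numpy()
    else:
        exposure = proteins.iloc[:, 0].to_numpy()
    rng = _rng(cfg2, "outcome")
    trait = theta * exposure
    if noise_sd > 0:
        trait = trait + rng.normal(0.0, noise_sd, size=len(trait))

    from .gwas import assoc_scan_matrix  # deferred: avoids import cycle at module load
    beta, se, pval = assoc_scan_matrix(genotypes.to_numpy(dtype=float),
                                       trait - trait.mean())
    G = genotypes.to_numpy(dtype=float)
    return pd.DataFrame({
        "variant_id": genotypes.columns,
        "chrom": variants["chrom"].to_numpy(),
        "pos": variants["pos"].to_numpy(),
        "effect_allele": variants["alt"].to_numpy(),
        "other_allele": variants["ref"].to_numpy(),
        "eaf": G.mean(axis=0) / 2.0,
        "beta": beta, "se": se, "pval": pval,
        "n": len(trait),
    })
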