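# Methods

This note documents the statistical procedures implemented in
`plasmapqtl`, the synthetic-cohort model used to exercise them, the
numerical choices made where the design was open, and what the passing
tests do and do not establish about real data.

## Normalization and imputation

Protein and peptide matrices enter on the log2 scale; non-positive raw
intensities are treated as missing. Features with fewer than 60% valid
values across samples are removed (boundary inclusive: exactly 60% is
kept). Remaining missing cells are imputed per **sample row** from a
downshifted normal, N(μ_s − 1.8 σ_s, (0.3 σ_s)²), where μ_s and σ_s are
the sample's observed mean and SD across features — mimicking values
below the detection limit. Imputation is seeded and deterministic; a
sample with fewer than two observed values is an error (its SD is
undefined).

The rank-based inverse normal transformation (INT) maps the observation
of rank r among N non-missing values to Φ⁻¹((r − c)/(N − 2c + 1)) with
the Blom offset c = 3/8. Ties receive average ranks before the
transform, which makes the INT deterministic and rank-preserving;
missing values stay missing and are excluded from N. Filtering precedes
imputation, and imputation precedes the INT.

## Association phenotypes

For genetic association, each protein's INT values are residualized by
OLS on age, sex (female = 1), BMI-SDS, obesity status (1 = obesity
clinic), obesity × BMI-SDS, plasma storage time and PC1
(complete-case), then re-standardized with a second INT. Peptides are
processed with the identical chain. The demographic model additionally
includes pubertal status, and can include age × BMI-SDS, sex × BMI-SDS
and age × sex interactions; Benjamini–Hochberg correction is applied
per term across proteins (the family is "proteins tested"), via the
statsmodels step-up implementation. Diagnostics report variance
inflation factors (1/(1 − R²) of each predictor on the rest) and
per-protein Shapiro–Wilk residual normality.

## Association testing

Associations are simple OLS of the residualized, re-INT phenotype on
alternate-allele dosage with intercept; the Wald P value uses the exact
t distribution with n − 2 degrees of freedom (exact under OLS and
asymptotically the usual Wald test). Synthetic cohorts are unrelated
and population-homogeneous by construction, so no mixed-model kinship
term is fitted; the covariate-adjustment contract is unchanged, and a
genotyping-batch column is accepted as an ordinary covariate if
supplied. Missing dosages are handled pairwise-complete; P values from
numerically perfect fits are floored at the smallest positive float
rather than reported as 0. Genotype QC order: variant call rate ≥ 95%,
MAF ≥ 0.05, Hardy–Weinberg χ² (1 df) P ≥ 1e-6, sample call rate ≥ 95%,
heterozygosity within ±3 s.d. of the cohort mean. Genomic inflation
λ_GC is the median association χ² over the 1-df χ² median (≈0.45494);
the implementation uses the exact `chi2.ppf(0.5, 1)` so that a scan
with all P = 0.5 gives λ = 1 identically.

## Primary pQTLs

Clumping is greedy: the smallest-P variant below 5 × 10⁻⁸ seeds a
clump, absorbing every unassigned variant with r² > 0.2 (pairwise
Pearson of dosages) within ±1 Mb on the same chromosome; ties on P
break toward the smaller genomic position. The cis window is anchored
at the transcription start site of the protein-coding gene (inclusive
at exactly 1 Mb; signed distances reported in transcription direction);
anchoring at gene boundaries is possible by supplying boundary
coordinates as the TSS column. Conditional signals come from exact
individual-level forward selection: selected lead dosages are added as
covariates and the region re-scanned while the minimum conditional P
stays below the genome-wide threshold (collinear dosages stop the
region). The study-wide threshold is 5 × 10⁻⁸ divided by the number of
proteins tested.

## Peptide tiers and artefact exclusion

Every primary pQTL is re-tested against all protein-group-specific
peptides of its protein at the peptide threshold 2.4 × 10⁻⁵ (a config
parameter; the printed value's exact divisor is not derivable from the
other constants, so it is adopted as-is). The decision tree:

- ≥ 2 significant peptides, all same sign → **Tier 1**; discordant
  signs → unclassified (surfaced, never dropped).
- exactly 1 significant peptide:
  - missense variant inside the coding gene whose encoded residue lies
    within the peptide ± 1 flanking residue → **excluded_artefact**;
  - otherwise, if the protein has > 3 testable peptides → unclassified;
  - else missense outside the gene → **Tier 2**; missense inside the
    gene, non-spanning peptide → **Tier 3**; synonymous → **Tier 4**.
- 0 significant peptides → unclassified.

Two deliberate choices: the one-residue flank captures cleavage-site
artefacts where the substitution abuts the peptide; and the artefact
exclusion is evaluated **before** the ≤ 3-peptide gate — that gate
restricts which pQTLs may earn tiers 2–4, whereas the exclusion rests
on positive evidence (the spanning peptide) and must apply regardless
of peptide count. Supporting peptides are tested against the lead
variant itself, not LD proxies. Direction concordance is judged among
significant peptides only; agreement with the protein-level sign is
reported but not required.

## Variance decomposition and effect sizes

Variance is decomposed on the INT scale by sequential (type-I) sums of
squares with the predictor order fixed as: independent pQTL dosages,
sex, age, obesity, BMI-SDS, BMI-SDS × obesity — the fixed order is what
makes type-I well defined. Component fractions are incremental
explained sums of squares over the total; by construction they sum to
the full-model R² (tiny negative increments from floating-point
cancellation, > −1e-8, are clipped to zero and noted). Age-strata
stability decomposes within 5–9, 10–14 and 15–20-year groups and
correlates the per-protein genetic fractions between groups.
Puberty/storage/PC1 pre-adjustment before decomposition is available
but off by default. Allelic fold changes are ratios of mean
**untransformed** (linear-scale) abundance in heterozygotes and
alternate homozygotes versus homozygous reference; empty genotype
groups yield flagged missing ratios.

## Prediction

Outer 70/30 train/test split, inner 70/30 train/validation split of the
training set. Features are ranked by |Pearson r| with the outcome on
the inner training set only; OLS models with the top k = 1..200
features are scored on the validation set. The selected k is the
smallest whose validation MSE is within 1% of the curve minimum (a
parsimony-preserving reading of "incremental decrease"; the full MSE
curve is emitted so any other rule can be re-applied). A small absolute
slack (1e-12 × validation outcome variance) keeps the rule stable when
the fit is numerically exact. The final model is refit on the full
training set and evaluated once on the held-out test set (MAE and
Pearson r). Ranking and selection provably never see test samples
(verified by label poisoning in the tests). BMI is predicted raw, not
age/sex-adjusted.

## Mendelian randomization and colocalization

Single-instrument Wald ratio at the top cis-pQTL: β_out/β_exp with
first-order delta SE se_out/|β_exp| and a two-sided normal P;
significance threshold 2.5 × 10⁻⁶ (0.05 over ~20,000 protein-coding
genes; a 2.3 × 10⁻⁶ variant of the threshold circulates — the value is
a parameter defaulting to 2.5 × 10⁻⁶). Effect alleles are harmonized by
(effect, other) pairs with sign flips for swapped alleles; palindromic
A/T and C/G variants are rejected because strand cannot be resolved
from alleles alone; |β_exp| < 1e-8 is a weak-instrument error.

Colocalization is the two-trait single-causal-variant
approximate-Bayes-factor model: per-variant Wakefield log-ABFs from
(β, se) with a N(0, 0.15²) effect prior for quantitative traits, and
hypothesis posteriors PP0–PP4 from prior per-SNP probabilities
p1 = p2 = 1e-4 (single-trait) and p12 = 1e-5 (shared), computed in log
space. A pair is colocalized when PP4 ≥ 0.7 and the regional
association 1 − PP0 − PP3 ≥ 0.6 (both configurable). Multi-trait
clustering is out of scope; the pairwise two-trait model is fully
specified mathematics and matches the pairwise framing of the analysis.

## Replication and novelty

Replication re-tests the discovery lead variant (no re-clumping)
against the same protein in an independently preprocessed cohort;
"replicated" means P < 0.05 with a concordant sign, and only pQTLs
whose variant and protein pass the replication cohort's own QC are
eligible. Note the sign requirement makes the null replication rate
0.025, not 0.05. Novelty: a pQTL is novel if no published record for
the same protein lies within ±1 Mb of the lead; matching is by exact
protein identifier and deliberately ignores LD.

## The synthetic cohort model

`simdata` draws genotypes under Hardy–Weinberg equilibrium (dosage ~
Binomial(2, MAF)) with a first-order copy-chain LD model: with
probability `ld_decay`, a sample's genotype at variant j is copied from
variant j − 1. This is not a coalescent — it produces the r² structure
the clumping rules need and nothing more. Covariates follow the study
population the pipeline targets: age ~ U(5, 20) years, sex ~
Bernoulli(0.5), BMI-SDS ~ N(0, 0.81²) in the general-population arm and
N(2.8, 0.75²) in the obesity-clinic arm (55% of the cohort), puberty a
logistic function of age with onset ~11 y, storage ~ U(0, 10) years
(the storage-effect magnitude on individual proteins is a free
parameter, as no reference value exists), PC1 ~ N(0, 1). Protein log2
values are baseline + planted genetic effects × dosage + covariate
terms + N(0, σ_p) noise; peptides are parent protein + fixed offset +
N(0, σ_pep). Artefact peptides are attenuated on the linear scale by
(2 − dosage)/2 — heterozygotes retain half the reference peptide,
alternate homozygotes none (undetected) — which is exactly the
dose-dependent detectability mechanism the tier framework targets, and
the planted protein-level effect of an artefact is zero by contract.
Missingness is MNAR: P(missing) = expit(intercept + slope × centred
log2 intensity) with a negative slope, so low-abundance features drop
out more. All randomness flows from one root seed through named
substreams, so stages re-run in isolation reproduce exactly.

What the generator does **not** emulate: ion statistics and
interference noise, batch structure, relatedness/pedigrees, population
stratification, realistic LD decay, or genotype imputation error.
Passing tests therefore establish correctness of the statistical
machinery under its stated assumptions, not robustness to those
real-data complications (in particular, the OLS substitution for a
mixed model is validated only for unrelated homogeneous cohorts).

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations to what
the checks need statistically: null calibration uses 10–20 cohorts of
500 samples × 200 proteins × 500 variants (1–2 million tests, binomial
SE of the P < 0.05 fraction ≈ 0.0002); effect recovery uses 120–200
replicates at n = 1,000; the tier fixture 800 samples with 50 genuine
and 20 artefact pQTLs; variance decomposition 20 seeds at n = 2,000,
where the per-seed sampling SD of an R² component is ≈0.012, so
recovery is judged on the Monte-Carlo mean across seeds; clumping is
checked against brute-force enumeration on 500–1,000 random ≤20-variant
instances. Degenerate inputs are errors, not silent results: constant
phenotypes, all-missing vectors, zero-variance proteins, collinear
covariates (named), empty age strata and empty genotype groups are all
rejected or flagged explicitly.
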