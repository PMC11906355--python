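"""Genotype quality control and per-feature association testing.

Association is ordinary least squares of a residualized, inverse-normal
transformed phenotype on alternate-allele dosage with an intercept; the
Wald P value comes from the exact t distribution with n − 2 degrees of
freedom.  Synthetic cohorts are unrelated and population-homogeneous, so no
kinship correction is applied; the phenotype-adjustment contract (covariate
residualization before scanning) is unchanged.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CohortBundle

__all__ = [
    "AssociationRecord",
    "QcReport",
    "qc_genotypes",
    "hwe_pvalue",
    "assoc_scan",
    "assoc_scan_matrix",
    "lambda_gc",
]

#: median of the chi-square distribution with 1 degree of freedom (~0.45494)
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

#: smallest P value reported (underflow guard for perfect fits)
P_FLOOR = 5e-324


@dataclasses.dataclass
class AssociationRecord:
    """One (variant, feature) association test."""

    variant_id: str
    feature_id: str
    feature_kind: str  # "protein" | "peptide"
    beta: float        # per alternate-allele dosage
    se: float
    p: float
    n: int
    maf: float
    failed: bool = False


@dataclasses.dataclass
class QcReport:
    """Counts of variants and samples removed at each genotype QC step."""

    n_variants_in: int = 0
    n_samples_in: int = 0
    variants_dropped_call_rate: int = 0
    variants_dropped_maf: int = 0
    variants_dropped_hwe: int = 0
    samples_dropped_call_rate: int = 0
    samples_dropped_heterozygosity: int = 0
    thresholds: dict = dataclasses.field(default_factory=dict)

    @property
    def n_variants_out(self) -> int:
        return (self.n_variants_in - self.variants_dropped_call_rate
                - self.variants_dropped_maf - self.variants_dropped_hwe)

    @property
    def n_samples_out(self) -> int:
        return (self.n_samples_in - self.samples_dropped_call_rate
                - self.samples_dropped_heterozygosity)


def hwe_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy–Weinberg chi-square test (1 df) on genotype counts.

    ``n_aa``/``n_ab``/``n_bb`` are homozygous-reference, heterozygous and
    homozygous-alternate counts.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_bb + n_ab) / (2.0 * n)
    q = 1.0 - p
    exp = np.array([q * q * n, 2 * p * q * n, p * p * n])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    nz = exp > 0
    chi2 = float(np.sum((obs[nz] - exp[nz]) ** 2 / exp[nz]))
    return float(stats.chi2.sf(chi2, df=1))


def qc_genotypes(bundle: CohortBundle, maf_min: float = 0.05,
                 hwe_p_min: float = 1e-6, var_call: float = 0.95,
                 sample_call: float = 0.95, het_sd: float = 3.0
                 ) -> tuple[CohortBundle, QcReport]:
    """Filter variants and samples, in the order: variant call rate, MAF,
    Hardy–Weinberg equilibrium, sample call rate, heterozygosity outliers
    (±``het_sd`` standard deviations from the mean heterozygosity rate).

    MAF filtering keeps variants with MAF ≥ ``maf_min``; HWE removes
    variants with P < ``hwe_p_min``.
    """
    report = QcReport(
        n_variants_in=bundle.genotypes.shape[1],
        n_samples_in=bundle.genotypes.shape[0],
        thresholds=dict(maf_min=maf_min, hwe_p_min=hwe_p_min, var_call=var_call,
                        sample_call=sample_call, het_sd=het_sd),
    )
    G = bundle.genotypes

    call = G.notna().mean(axis=0)
    keep = call >= var_call
    report.variants_dropped_call_rate = int((~keep).sum())
    G = G.loc[:, keep]

    af = G.mean(axis=0, skipna=True) / 2.0
    maf = np.minimum(af, 1.0 - af)
    keep = maf >= maf_min
    report.variants_dropped_maf = int((~keep).sum())
    G = G.loc[:, keep]

    hwe_p = np.array([
        hwe_pvalue(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        for _, col in G.items()
    ]) if G.shape[1] else np.array([])
    keep = hwe_p >= hwe_p_min
    report.variants_dropped_hwe = int((~keep).sum())
    G = G.loc[:, keep]
    if G.shape[1] == 0:
        raise ValueError("genotype QC removed every variant")

    s_call = G.notna().mean(axis=1)
    keep_s = s_call >= sample_call
    report.samples_dropped_call_rate = int((~keep_s).sum())
    G = G.loc[keep_s]

    het = (G == 1).mean(axis=1)
    mu, sd = het.mean(), het.std(ddof=1)
    if sd > 0:
        keep_h = (het - mu).abs() <= het_sd * sd
    else:
        keep_h = pd.Series(True, index=G.index)
    report.samples_dropped_heterozygosity = int((~keep_h).sum())
    G = G.loc[keep_h]

    out = CohortBundle(
        genotypes=G,
        variants=bundle.variants.loc[G.columns],
        proteins=bundle.proteins.loc[G.index],
        protein_genes=bundle.protein_genes,
        peptides=bundle.peptides.loc[G.index],
        peptide_map=bundle.peptide_map,
        covariates=bundle.covariates.loc[G.index],
    )
    return out, report


def assoc_scan_matrix(G: np.ndarray, y: np.ndarray,
                      X_cond: np.ndarray | None = None):
    """Vectorized simple OLS of phenotype ``y`` on each dosage column of ``G``.

    Fits y ~ 1 + g (plus optional conditioning covariates ``X_cond``, whose
    effect is projected out of both y and g first — exact forward-selection
    conditioning).  Missing dosages are handled pairwise-complete.  Returns
    ``(beta, se, p)`` arrays; columns with zero in-sample dosage variance
    yield NaN.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    if np.nanstd(y) == 0:
        raise ValueError("constant phenotype")

    k_cond = 0
    if X_cond is not None and X_cond.size:
        X = np.column_stack([np.ones(n), X_cond])
        k_cond = X_cond.shape[1]
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        y = y - X @ coef
        coefs, *_ = np.linalg.lstsq(X, G, rcond=None)
        G = G - X @ coefs

    has_nan = np.isnan(G).any() or np.isnan(y).any()
    if not has_nan:
        gm = G.mean(axis=0)
        Gc = G - gm
        yc = y - y.mean()
        sxx = np.einsum("ij,ij->j", Gc, Gc)
        sxy = yc @ Gc
        syy = float(yc @ yc)
        n_eff = np.full(m, n)
    else:
        obs = np.isfinite(G) & np.isfinite(y)[:, None]
        Gz = np.where(obs, G, 0.0)
        yz = np.where(np.isfinite(y), y, 0.0)
        n_eff = obs.sum(axis=0)
        gm = np.divide(Gz.sum(axis=0), n_eff,
                       out=np.zeros(m), where=n_eff > 0)
        ym = np.divide((yz[:, None] * obs).sum(axis=0), n_eff,
                       out=np.zeros(m), where=n_eff > 0)
        Gc = np.where(obs, G - gm, 0.0)
        yc = np.where(obs, yz[:, None] - ym, 0.0)
        sxx = np.einsum("ij,ij->j", Gc, Gc)
        sxy = np.einsum("ij,ij->j", Gc, yc)
        syy = np.einsum("ij,ij->j", yc, yc)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        dof = n_eff - 2 - k_cond
        sigma2 = np.clip(rss, 0.0, None) / np.maximum(dof, 1)
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(dof, 1))
    bad = (sxx <= 0) | (dof < 1)
    beta[bad] = np.nan
    se[bad] = np.nan
    p[bad] = np.nan
    # perfect fits underflow the t tail; report the smallest positive float
    p = np.where(np.isfinite(beta) & (p <= 0), P_FLOOR, p)
    return beta, se, p


def assoc_scan(bundle: CohortBundle, phenotype: pd.Series | np.ndarray,
               feature_id: str, feature_kind: str = "protein",
               variant_ids: list[str] | None = None) -> list[AssociationRecord]:
    """Scan every (QC-passed) variant against one phenotype vector.

    The phenotype must already be residualized and re-INT standardized.
    Variants with zero in-sample minor allele count are skipped.
    """
    G = bundle.genotypes if variant_ids is None else bundle.genotypes[variant_ids]
    y = np.asarray(phenotype, dtype=float)
    if len(y) != G.shape[0]:
        raise ValueError("phenotype length does not match cohort size")
    beta, se, p = assoc_scan_matrix(G.to_numpy(dtype=float), y)
    af = G.mean(axis=0, skipna=True).to_numpy() / 2.0
    maf = np.minimum(af, 1.0 - af)
    n_obs = (G.notna() & np.isfinite(y)[:, None]).sum(axis=0).to_numpy()
    records = []
    for j, vid in enumerate(G.columns):
        if maf[j] <= 0:
            continue
        records.append(AssociationRecord(
            variant_id=vid, feature_id=feature_id, feature_kind=feature_kind,
            beta=float(beta[j]), se=float(se[j]), p=float(p[j]),
            n=int(n_obs[j]), maf=float(maf[j]),
            failed=not np.isfinite(beta[j]),
        ))
    return records


def lambda_gc(p_values) -> float:
    """Genomic-control inflation factor.

    Median of the association chi-square statistics (from the 1-df quantile
    transform of the P values) divided by the 1-df chi-square median ≈0.45494.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("lambda_gc requires at least one P value")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)
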