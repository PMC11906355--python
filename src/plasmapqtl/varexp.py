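"""Variance decomposition of protein levels and pQTL effect sizes.

Decomposition uses sequential (type-I) sums of squares: predictor blocks
are added in the fixed order — independent pQTL dosages, sex, age, obesity
status, BMI-SDS, BMI-SDS × obesity — and each block's contribution is the
increase in explained sum of squares over the total sum of squares.  The
order makes the type-I decomposition well defined; by construction the
component fractions sum to the full-model R².

Effect sizes are also expressed as allelic fold changes: ratios of mean
protein abundance on the untransformed (linear) scale between heterozygote
or alternate-homozygote carriers and the homozygous-reference group.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_formats import CohortBundle

__all__ = [
    "VarianceDecomposition",
    "EffectSize",
    "COMPONENT_ORDER",
    "decompose_variance",
    "age_group_stability",
    "allelic_fold_change",
    "AGE_GROUPS",
]

COMPONENT_ORDER = ["pqtls", "sex", "age", "obesity", "bmi_sds", "bmi_sds_x_obesity"]

AGE_GROUPS = [(5.0, 9.0), (10.0, 14.0), (15.0, 20.0)]


@dataclasses.dataclass
class VarianceDecomposition:
    """Per-protein ordered component → incremental variance fraction."""

    protein_id: str
    fractions: dict[str, float]
    total_r2: float
    n: int


@dataclasses.dataclass
class EffectSize:
    """Allelic fold change of one (variant, protein) pair.

    ``afc_het``/``afc_hom`` are mean-abundance ratios of heterozygotes and
    alternate homozygotes to the homozygous-reference group on the linear
    scale, without any transformation.
    """

    variant_id: str
    protein_id: str
    afc_het: float
    afc_hom: float
    log2_fc_hom: float
    n_by_genotype: tuple[int, int, int]


def _blocks(bundle: CohortBundle, independent_leads: list[str]):
    cov = bundle.covariates
    return [
        ("pqtls", bundle.genotypes[independent_leads].to_numpy(dtype=float)
         if independent_leads else np.empty((bundle.n_samples, 0))),
        ("sex", cov[["sex"]].to_numpy(dtype=float)),
        ("age", cov[["age"]].to_numpy(dtype=float)),
        ("obesity", cov[["obesity"]].to_numpy(dtype=float)),
        ("bmi_sds", cov[["bmi_sds"]].to_numpy(dtype=float)),
        ("bmi_sds_x_obesity",
         (cov["bmi_sds"] * cov["obesity"]).to_numpy(dtype=float)[:, None]),
    ]


def decompose_variance(bundle: CohortBundle, protein_id: str,
                       independent_leads: list[str],
                       phenotype: np.ndarray | None = None
                       ) -> VarianceDecomposition:
    """Sequential-SS decomposition of one protein's variance.

    ``independent_leads`` are the conditionally independent pQTL lead
    variants of this protein.  ``phenotype`` overrides the bundle's protein
    column (e.g. to decompose the INT scale used for association).  Tiny
    negative increments from floating-point cancellation are clipped to 0.
    """
    y = (bundle.proteins[protein_id].to_numpy(dtype=float)
         if phenotype is None else np.asarray(phenotype, dtype=float))
    blocks = _blocks(bundle, independent_leads)
    obs = np.isfinite(y)
    for _, B in blocks:
        if B.size:
            obs &= np.isfinite(B).all(axis=1)
    y = y[obs]
    n = y.size
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError(f"protein {protein_id} has zero variance")

    X = np.ones((n, 1))
    prev_ess = 0.0
    fractions: dict[str, float] = {}
    for name, B in blocks:
        if B.size:
            X = np.column_stack([X, B[obs]])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        ess = tss - float(resid @ resid)
        frac = (ess - prev_ess) / tss
        fractions[name] = max(frac, 0.0) if frac > -1e-8 else frac
        prev_ess = ess
    total_r2 = prev_ess / tss
    return VarianceDecomposition(protein_id=protein_id, fractions=fractions,
                                 total_r2=total_r2, n=n)


def age_group_stability(bundle: CohortBundle, leads_by_protein: dict[str, list[str]],
                        groups: list[tuple[float, float]] = AGE_GROUPS,
                        min_n: int = 30,
                        phenotypes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Stability of genetic variance fractions across age strata.

    Decomposes each protein within each age group and returns the pairwise
    Pearson correlation matrix of the per-protein pQTL variance fractions
    between groups.
    """
    age = bundle.covariates["age"]
    frac_by_group: dict[str, pd.Series] = {}
    for gi, (lo, hi) in enumerate(groups):
        mask = (age >= lo) & (age <= hi)
        label = f"{lo:g}-{hi:g}"
        if label in frac_by_group:  # identical ranges must stay distinct
            label = f"{label}#{gi}"
        if mask.sum() < min_n:
            raise ValueError(f"age group {label} has fewer than {min_n} samples")
        sub = bundle.subset_samples(bundle.covariates.index[mask])
        sub_ph = phenotypes.loc[mask] if phenotypes is not None else None
        fracs = {}
        for pid, leads in leads_by_protein.items():
            y = sub_ph[pid].to_numpy(dtype=float) if sub_ph is not None else None
            try:
                d = decompose_variance(sub, pid, leads, phenotype=y)
            except ValueError:
                continue
            fracs[pid] = d.fractions["pqtls"]
        frac_by_group[label] = pd.Series(fracs)
    df = pd.DataFrame(frac_by_group).dropna()
    return df.corr(method="pearson")


def allelic_fold_change(raw_abundance: pd.Series | np.ndarray,
                        dosage: pd.Series | np.ndarray,
                        variant_id: str = "", protein_id: str = "") -> EffectSize:
    """Fold change of mean untransformed abundance by genotype group.

    ``raw_abundance`` must be linear-scale (not log) and non-negative;
    groups with no carriers yield NaN ratios.
    """
    x = np.asarray(raw_abundance, dtype=float)
    g = np.asarray(dosage, dtype=float)
    obs = np.isfinite(x) & np.isfinite(g)
    x, g = x[obs], g[obs]
    if (x < 0).any():
        raise ValueError("raw abundances must be non-negative")
    means, counts = [], []
    for k in (0, 1, 2):
        sel = g == k
        counts.append(int(sel.sum()))
        means.append(float(x[sel].mean()) if sel.any() else np.nan)
    m0, m1, m2 = means
    afc_het = m1 / m0 if counts[0] and counts[1] else np.nan
    afc_hom = m2 / m0 if counts[0] and counts[2] else np.nan
    log2fc = float(np.log2(afc_hom)) if np.isfinite(afc_hom) and afc_hom > 0 else np.nan
    return EffectSize(variant_id=variant_id, protein_id=protein_id,
                      afc_het=afc_het, afc_hom=afc_hom, log2_fc_hom=log2fc,
                      n_by_genotype=tuple(counts))
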