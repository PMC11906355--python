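"""Peptide-level validation of primary pQTLs: artefact exclusion and tiers.

A protein-altering variant can create an apparent pQTL without any change
in protein abundance: the peptide spanning the substituted residue is only
detected in its reference form, so its measured intensity tracks
reference-allele count.  Every primary pQTL is therefore re-tested against
the protein's peptides; the pattern of significant peptide associations
assigns a confidence tier:

* Tier 1 — at least two supporting peptides, directionally concordant.
* Tier 2 — one supporting peptide; variant non-synonymous, outside the
  protein-coding gene.
* Tier 3 — one supporting peptide; variant non-synonymous, inside the
  protein-coding gene, and the encoded substitution is NOT part of the
  supporting peptide.
* Tier 4 — one supporting peptide; variant synonymous.
* excluded_artefact — the single supporting peptide spans the substituted
  residue (± a one-residue cleavage flank) of a non-synonymous variant
  inside the gene: the dose-dependent detectability artefact.
* unclassified — no supporting peptide, discordant multi-peptide support,
  or single-peptide support that matches no tier rule.

For tiers 2–4 the total number of testable peptides must not exceed three.
The artefact exclusion is checked before that gate: the exclusion rests on
positive evidence (the spanning peptide), not on the peptide count.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .gwas import assoc_scan_matrix
from .io_formats import CohortBundle
from .pqtl import PqtlRecord

__all__ = [
    "TierRecord",
    "PEPTIDE_ALPHA",
    "peptide_support",
    "spans_variant",
    "assign_tier",
    "concordance_summary",
    "tier_pqtls",
]

#: peptide-level significance threshold, adjusted for the number of primary
#: variant-protein associations
PEPTIDE_ALPHA = 2.4e-5


@dataclasses.dataclass
class TierRecord:
    """Peptide-level evidence and tier for one primary pQTL."""

    variant_id: str
    protein_id: str
    n_peptides_total: int
    n_peptides_significant: int
    directions: list[int]                    # signs of significant peptide betas
    significant_peptides: list[str]
    consequence: str                         # missense | synonymous | other
    in_coding_gene: bool
    aa_pos: float | None
    spanning: bool                           # a significant peptide covers the residue
    tier: str = "unassigned"
    reason: str = ""


def spans_variant(aa_start: int, aa_end: int, aa_pos: float,
                  flank: int = 1) -> bool:
    """True iff the substituted residue lies within the peptide ± flank.

    Coordinates are 1-based inclusive; the default one-residue flank
    captures cleavage-site artefacts, where the substitution abuts the
    peptide rather than lying inside it.
    """
    if aa_pos is None or not np.isfinite(aa_pos):
        raise ValueError("aa_pos is required for a coding variant")
    return (aa_start - flank) <= aa_pos <= (aa_end + flank)


def peptide_support(bundle: CohortBundle, pqtl: PqtlRecord,
                    peptide_phenotypes: pd.DataFrame,
                    alpha_pep: float = PEPTIDE_ALPHA,
                    flank: int = 1) -> TierRecord:
    """Test every peptide of the pQTL's protein against its lead variant.

    ``peptide_phenotypes`` must be preprocessed identically to the protein
    phenotypes (filter → impute → INT → residualize → re-INT).  Peptides of
    the protein absent from that matrix (dropped in QC) are not testable.
    """
    pep_ids = [p for p in bundle.peptide_map.index[
        bundle.peptide_map["protein_id"] == pqtl.protein_id]
        if p in peptide_phenotypes.columns]
    variant = bundle.variants.loc[pqtl.lead_variant]
    consequence = str(variant["consequence"])
    gene = (bundle.protein_genes.loc[pqtl.protein_id, "gene_id"]
            if pqtl.protein_id in bundle.protein_genes.index else None)
    in_gene = bool(gene) and str(variant["gene_id"]) == str(gene)
    aa_pos = float(variant["aa_pos"]) if np.isfinite(variant["aa_pos"]) else None

    if not pep_ids:
        return TierRecord(
            variant_id=pqtl.lead_variant, protein_id=pqtl.protein_id,
            n_peptides_total=0, n_peptides_significant=0, directions=[],
            significant_peptides=[], consequence=consequence,
            in_coding_gene=in_gene, aa_pos=aa_pos, spanning=False,
            tier="unclassified", reason="no testable peptides",
        )

    g = bundle.genotypes[pqtl.lead_variant].to_numpy(dtype=float)[:, None]
    sig, dirs = [], []
    for pep in pep_ids:
        y = peptide_phenotypes[pep].to_numpy(dtype=float)
        if np.nanstd(y) == 0:
            continue
        beta, se, p = assoc_scan_matrix(g, y)
        if np.isfinite(p[0]) and p[0] < alpha_pep:
            sig.append(pep)
            dirs.append(int(np.sign(beta[0])))

    spanning = False
    if aa_pos is not None:
        for pep in sig:
            row = bundle.peptide_map.loc[pep]
            if spans_variant(int(row["aa_start"]), int(row["aa_end"]), aa_pos,
                             flank=flank):
                spanning = True
                break

    return TierRecord(
        variant_id=pqtl.lead_variant, protein_id=pqtl.protein_id,
        n_peptides_total=len(pep_ids), n_peptides_significant=len(sig),
        directions=dirs, significant_peptides=sig, consequence=consequence,
        in_coding_gene=in_gene, aa_pos=aa_pos, spanning=spanning,
    )


def assign_tier(record: TierRecord) -> TierRecord:
    """Assign the confidence tier (total, deterministic decision tree)."""
    n_sig = record.n_peptides_significant
    if record.tier == "unclassified":
        return record
    if n_sig == 0:
        record.tier = "unclassified"
        record.reason = "no supporting peptide"
    elif n_sig >= 2:
        if len(set(record.directions)) == 1:
            record.tier = "1"
        else:
            record.tier = "unclassified"
            record.reason = "discordant peptide directions"
    else:  # exactly one supporting peptide
        nonsyn = record.consequence == "missense"
        if nonsyn and record.in_coding_gene and record.spanning:
            record.tier = "excluded_artefact"
            record.reason = "single supporting peptide spans the substituted residue"
        elif record.n_peptides_total > 3:
            record.tier = "unclassified"
            record.reason = "single supporting peptide but >3 testable peptides"
        elif record.consequence == "synonymous":
            record.tier = "4"
        elif nonsyn and not record.in_coding_gene:
            record.tier = "2"
        elif nonsyn and record.in_coding_gene:
            record.tier = "3"
        else:
            record.tier = "unclassified"
            record.reason = "single peptide, variant neither missense nor synonymous"
    return record


def concordance_summary(records: list[TierRecord]) -> float:
    """Fraction of multi-peptide pQTLs whose significant peptides all share
    one direction of effect.  Undefined (ValueError) on empty input."""
    multi = [r for r in records if r.n_peptides_significant >= 2]
    if not multi:
        raise ValueError("no records with >=2 significant peptides")
    conc = sum(1 for r in multi if len(set(r.directions)) == 1)
    return conc / len(multi)


def tier_pqtls(bundle: CohortBundle, pqtls: list[PqtlRecord],
               peptide_phenotypes: pd.DataFrame,
               alpha_pep: float = PEPTIDE_ALPHA, flank: int = 1
               ) -> list[TierRecord]:
    """Peptide support + tier assignment for a list of primary pQTLs."""
    return [
        assign_tier(peptide_support(bundle, q, peptide_phenotypes,
                                    alpha_pep=alpha_pep, flank=flank))
        for q in pqtls
    ]
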