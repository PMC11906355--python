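"""Primary-pQTL mapping: LD, clumping, cis/trans labels, conditional signals.

A primary pQTL is the most significant variant of an LD clump (r² > 0.2
within ±1 Mb) reaching the genome-wide threshold (P < 5 × 10⁻⁸) for a
protein.  It is labelled *cis* if it lies within ±1 Mb of the transcription
start site of the protein-coding gene, *trans* otherwise.  Conditionally
independent signals are found by exact individual-level forward selection,
re-fitting the association with already-selected leads as covariates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .gwas import AssociationRecord, assoc_scan_matrix
from .io_formats import CohortBundle

__all__ = [
    "PqtlRecord",
    "ld_r2",
    "clump",
    "classify_cis_trans",
    "conditional_scan",
    "study_wide_threshold",
    "discover_pqtls",
    "GENOME_WIDE_P",
    "CIS_WINDOW_BP",
]

GENOME_WIDE_P = 5e-8
CIS_WINDOW_BP = 1_000_000
LD_R2_MIN = 0.2


@dataclasses.dataclass
class PqtlRecord:
    """A primary pQTL for one protein."""

    protein_id: str
    lead_variant: str
    clump_members: list[str]
    p_lead: float
    beta_lead: float
    se_lead: float
    cis: bool | None = None
    tss_distance: int | None = None  # signed bp; negative = upstream by strand
    conditional_rank: int | None = None
    significance: str = "genome-wide"  # "genome-wide" | "study-wide"


def ld_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of two dosage vectors
    (pairwise-complete samples)."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    obs = np.isfinite(a) & np.isfinite(b)
    a, b = a[obs], b[obs]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("LD r² requires two non-constant dosage vectors")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(records: list[AssociationRecord], genotypes: pd.DataFrame,
          positions: pd.Series, r2_min: float = LD_R2_MIN,
          window_bp: float = CIS_WINDOW_BP, p_max: float = GENOME_WIDE_P,
          chroms: pd.Series | None = None) -> list[PqtlRecord]:
    """Greedy LD clumping of one protein's association records.

    Repeatedly takes the smallest-P unassigned variant with P < ``p_max``
    as a lead and assigns to its clump every unassigned variant with
    r² > ``r2_min`` and |pos − lead_pos| ≤ ``window_bp`` on the same
    chromosome.  Ties on P break toward the smaller genomic position.
    """
    sig = [r for r in records if not r.failed and np.isfinite(r.p) and r.p < p_max]
    missing = [r.variant_id for r in sig if r.variant_id not in genotypes.columns]
    if missing:
        raise ValueError(f"genotype columns missing for records: {missing[:5]}")
    by_id = {r.variant_id: r for r in sig}
    unassigned = set(by_id)
    out: list[PqtlRecord] = []
    while unassigned:
        lead_id = min(unassigned,
                      key=lambda v: (by_id[v].p, int(positions[v])))
        lead = by_id[lead_id]
        members = [lead_id]
        g_lead = genotypes[lead_id].to_numpy(dtype=float)
        for vid in sorted(unassigned - {lead_id}, key=lambda v: int(positions[v])):
            if chroms is not None and chroms[vid] != (chroms[lead_id]):
                continue
            if abs(int(positions[vid]) - int(positions[lead_id])) > window_bp:
                continue
            try:
                r2 = ld_r2(g_lead, genotypes[vid].to_numpy(dtype=float))
            except ValueError:
                continue
            if r2 > r2_min:
                members.append(vid)
        unassigned -= set(members)
        out.append(PqtlRecord(
            protein_id=lead.feature_id, lead_variant=lead_id,
            clump_members=members, p_lead=lead.p, beta_lead=lead.beta,
            se_lead=lead.se,
        ))
    out.sort(key=lambda r: (r.p_lead, int(positions[r.lead_variant])))
    return out


def classify_cis_trans(record: PqtlRecord, variants: pd.DataFrame,
                       protein_genes: pd.DataFrame,
                       window_bp: int = CIS_WINDOW_BP) -> PqtlRecord:
    """Label a pQTL cis/trans relative to the protein-coding gene's TSS.

    *cis*: lead variant on the gene's chromosome within ±``window_bp`` of
    the TSS (inclusive at exactly the window edge).  The signed distance is
    reported in transcription direction (negative = upstream).  Proteins
    without a mapped gene get ``cis=None`` and are excluded from cis/trans
    summaries.
    """
    if record.protein_id not in protein_genes.index:
        record.cis = None
        record.tss_distance = None
        return record
    gene = protein_genes.loc[record.protein_id]
    v = variants.loc[record.lead_variant]
    if str(v["chrom"]) != str(gene["chrom"]):
        record.cis = False
        record.tss_distance = None
        return record
    raw = int(v["pos"]) - int(gene["tss"])
    record.tss_distance = raw if gene.get("strand", "+") == "+" else -raw
    record.cis = abs(raw) <= window_bp
    return record


def conditional_scan(bundle: CohortBundle, phenotype, leads: list[PqtlRecord],
                     p_max: float = GENOME_WIDE_P, max_iter: int = 10,
                     window_bp: int = CIS_WINDOW_BP) -> list[PqtlRecord]:
    """Forward selection of conditionally independent signals per region.

    Regions are the ±``window_bp`` neighbourhoods of the supplied clump
    leads (merged when overlapping on one chromosome).  Within each region
    the strongest variant is selected, then the scan is re-fit with the
    selected dosages as covariates; selection continues while the minimum
    conditional P stays below ``p_max`` (or ``max_iter`` signals).  Returns
    records ranked 1, 2, ... per region; rank 1 is the primary signal.
    """
    y = np.asarray(phenotype, dtype=float)
    variants = bundle.variants
    out: list[PqtlRecord] = []

    regions: list[tuple[str, int, int, str]] = []  # chrom, lo, hi, protein
    for lead in sorted(leads, key=lambda r: r.p_lead):
        chrom = str(variants.loc[lead.lead_variant, "chrom"])
        pos = int(variants.loc[lead.lead_variant, "pos"])
        lo, hi = pos - window_bp, pos + window_bp
        merged = False
        for i, (c, a, b, pid) in enumerate(regions):
            if c == chrom and pid == lead.protein_id and not (hi < a or lo > b):
                regions[i] = (c, min(a, lo), max(b, hi), pid)
                merged = True
                break
        if not merged:
            regions.append((chrom, lo, hi, lead.protein_id))

    for chrom, lo, hi, protein_id in regions:
        in_region = variants.index[
            (variants["chrom"].astype(str) == chrom)
            & (variants["pos"] >= lo) & (variants["pos"] <= hi)
        ]
        in_region = [v for v in in_region if v in bundle.genotypes.columns]
        if not in_region:
            continue
        G = bundle.genotypes[in_region].to_numpy(dtype=float)
        selected: list[int] = []
        for rank in range(1, max_iter + 1):
            X_cond = G[:, selected] if selected else None
            if X_cond is not None and np.linalg.matrix_rank(
                    np.column_stack([np.ones(len(y)), X_cond])) < X_cond.shape[1] + 1:
                break  # collinear selected dosages: stop region
            beta, se, p = assoc_scan_matrix(G, y, X_cond=X_cond)
            p = p.copy()
            p[selected] = np.nan
            if not np.isfinite(p).any():
                break
            j = int(np.nanargmin(p))
            if not (p[j] < p_max):
                break
            vid = in_region[j]
            out.append(PqtlRecord(
                protein_id=protein_id, lead_variant=vid, clump_members=[vid],
                p_lead=float(p[j]), beta_lead=float(beta[j]), se_lead=float(se[j]),
                conditional_rank=rank,
            ))
            selected.append(j)
    return out


def study_wide_threshold(alpha_gw: float = GENOME_WIDE_P,
                         n_proteins: int = 1) -> float:
    """Bonferroni-style study-wide threshold: ``alpha_gw / n_proteins``."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    return alpha_gw / n_proteins


def discover_pqtls(bundle: CohortBundle, phenotypes: pd.DataFrame,
                   p_max: float = GENOME_WIDE_P, r2_min: float = LD_R2_MIN,
                   window_bp: int = CIS_WINDOW_BP,
                   study_wide_p: float | None = None) -> list[PqtlRecord]:
    """Scan + clump + classify for every protein phenotype column.

    ``phenotypes`` are the residualized re-INT protein values (samples
    aligned with the bundle).  Records are flagged study-wide significant
    when ``p_lead < study_wide_p`` (default 5e-8 / number of proteins).
    """
    from .gwas import assoc_scan

    if study_wide_p is None:
        study_wide_p = study_wide_threshold(p_max, phenotypes.shape[1])
    positions = bundle.variants["pos"]
    chroms = bundle.variants["chrom"].astype(str)
    out: list[PqtlRecord] = []
    for pid in phenotypes.columns:
        y = phenotypes[pid].to_numpy(dtype=float)
        if np.nanstd(y) == 0:
            continue
        records = assoc_scan(bundle, y, feature_id=pid, feature_kind="protein")
        clumps = clump(records, bundle.genotypes, positions,
                       r2_min=r2_min, window_bp=window_bp, p_max=p_max,
                       chroms=chroms)
        for rec in clumps:
            rec = classify_cis_trans(rec, bundle.variants, bundle.protein_genes,
                                     window_bp=window_bp)
            if rec.p_lead < study_wide_p:
                rec.significance = "study-wide"
            out.append(rec)
    return out
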