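"""Replication of discovered pQTLs in an independent cohort and novelty
assessment against published pQTL lists.

Replication re-tests each discovery lead variant (no re-clumping) against
the same protein in a replication cohort preprocessed with the identical
pipeline; a pQTL replicates when the replication P is below the nominal
threshold (0.05) with the same direction of effect.  Novelty: a primary
pQTL is novel when no published variant within ±1 Mb of its lead has been
reported for the same protein (LD is deliberately not considered).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as _st

from .gwas import assoc_scan_matrix
from .io_formats import CohortBundle
from .pqtl import PqtlRecord

__all__ = ["ReplicationRecord", "replicate", "replication_summary",
           "assess_novelty"]


@dataclasses.dataclass
class ReplicationRecord:
    """Discovery vs replication evidence for one pQTL."""

    variant_id: str
    protein_id: str
    discovery_beta: float
    discovery_se: float
    discovery_p: float
    eligible: bool
    replication_beta: float = np.nan
    replication_se: float = np.nan
    replication_p: float = np.nan
    replicated: bool = False
    cis: bool | None = None
    novel: bool | None = None


def replicate(pqtls: list[PqtlRecord], replication: CohortBundle,
              phenotypes: pd.DataFrame, alpha: float = 0.05
              ) -> list[ReplicationRecord]:
    """Re-test discovery pQTLs in a replication cohort.

    ``phenotypes`` are the replication cohort's residualized re-INT protein
    values.  A pQTL is eligible when its lead variant passed the
    replication cohort's genotype QC and the protein its proteomics QC;
    ineligible pQTLs are kept with ``eligible=False``.
    """
    out = []
    for q in pqtls:
        rec = ReplicationRecord(
            variant_id=q.lead_variant, protein_id=q.protein_id,
            discovery_beta=q.beta_lead, discovery_se=q.se_lead,
            discovery_p=q.p_lead, cis=q.cis,
            eligible=(q.lead_variant in replication.genotypes.columns
                      and q.protein_id in phenotypes.columns),
        )
        if rec.eligible:
            g = replication.genotypes[q.lead_variant].to_numpy(dtype=float)[:, None]
            y = phenotypes[q.protein_id].to_numpy(dtype=float)
            beta, se, p = assoc_scan_matrix(g, y)
            rec.replication_beta = float(beta[0])
            rec.replication_se = float(se[0])
            rec.replication_p = float(p[0])
            rec.replicated = bool(
                np.isfinite(p[0]) and p[0] < alpha
                and np.sign(beta[0]) == np.sign(q.beta_lead)
            )
        out.append(rec)
    if not any(r.eligible for r in out):
        raise ValueError("no pQTLs eligible for replication")
    return out


def replication_summary(records: list[ReplicationRecord]) -> dict:
    """Replication rate overall and by cis/trans/novel, plus the Pearson
    correlation between discovery and replication betas (eligible pQTLs)."""
    elig = [r for r in records if r.eligible]
    def _rate(rs):
        return float(np.mean([r.replicated for r in rs])) if rs else np.nan
    betas_d = [r.discovery_beta for r in elig]
    betas_r = [r.replication_beta for r in elig]
    beta_r = (float(_st.pearsonr(betas_d, betas_r)[0])
              if len(elig) > 2 else np.nan)
    return {
        "n_eligible": len(elig),
        "rate": _rate(elig),
        "rate_cis": _rate([r for r in elig if r.cis is True]),
        "rate_trans": _rate([r for r in elig if r.cis is False]),
        "rate_novel": _rate([r for r in elig if r.novel is True]),
        "beta_pearson_r": beta_r,
    }


def assess_novelty(pqtls: list[PqtlRecord], published: pd.DataFrame,
                   variants: pd.DataFrame, window_bp: int = 1_000_000
                   ) -> pd.DataFrame:
    """Flag each primary pQTL as novel vs previously reported.

    ``published`` needs columns ``protein_id, chrom, pos``.  A pQTL is
    novel iff no published row for the same protein lies within
    ±``window_bp`` of the lead (same chromosome).  Proteins absent from the
    published list are novel by definition; pQTLs whose protein identifier
    cannot be matched are counted in ``.attrs['n_unmatched']`` = 0 here
    since matching is by exact identifier.
    """
    need = {"protein_id", "chrom", "pos"}
    if not need.issubset(published.columns):
        raise ValueError(f"published list must have columns {sorted(need)}")
    rows = []
    for q in pqtls:
        chrom = str(variants.loc[q.lead_variant, "chrom"])
        pos = int(variants.loc[q.lead_variant, "pos"])
        prev = published[(published["protein_id"] == q.protein_id)
                         & (published["chrom"].astype(str) == chrom)
                         & ((published["pos"] - pos).abs() <= window_bp)]
        rows.append((q.lead_variant, q.protein_id, prev.empty))
    return pd.DataFrame(rows, columns=["variant_id", "protein_id", "novel"])
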