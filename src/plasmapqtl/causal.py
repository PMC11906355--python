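"""Two-sample Mendelian randomization and Bayesian colocalization.

MR uses the single-instrument Wald ratio: the causal effect of a protein on
an outcome trait is estimated at the top cis-pQTL as
beta_outcome / beta_exposure, with the first-order delta-method standard
error se_outcome / |beta_exposure| and a two-sided normal P value.  The
default significance threshold, 2.5 × 10⁻⁶, corrects 0.05 for ~20,000
protein-coding genes.

Colocalization is the two-trait approximate-Bayes-factor model under a
single-causal-variant assumption: per variant, Wakefield's approximate
Bayes factor is computed from (beta, se) with a N(0, prior_sd²) effect
prior, and the five hypothesis posteriors are

    H0 — no association with either trait,
    H1/H2 — association with trait A/B only,
    H3 — both traits, distinct causal variants,
    H4 — both traits, one shared causal variant,

with prior per-SNP probabilities p1, p2 (single-trait) and p12 (shared).
A pair is flagged colocalized when PP4 ≥ 0.7; the regional-association
criterion maps to 1 − PP0 − PP3 ≥ 0.6 (configurable).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "CausalResult",
    "HarmonizationError",
    "MR_ALPHA",
    "wald_ratio",
    "harmonize",
    "coloc_abf",
]

#: MR significance: 0.05 corrected for the number of protein-coding genes
MR_ALPHA = 2.5e-6

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class HarmonizationError(ValueError):
    """Effect alleles of the two studies cannot be reconciled."""


@dataclasses.dataclass
class CausalResult:
    """MR estimate and colocalization posteriors for a (protein, trait) pair."""

    protein_id: str
    trait_id: str
    instrument: str
    wald_beta: float
    wald_se: float
    wald_p: float
    mr_significant: bool
    pp: np.ndarray | None = None        # PP0..PP4
    colocalized: bool | None = None


def harmonize(exposure: pd.Series, outcome: pd.Series,
              drop_palindromic: bool = True) -> tuple[float, float]:
    """Align the outcome effect to the exposure's effect allele.

    Both rows follow the summary-stats schema.  If the outcome's effect and
    other alleles are swapped relative to the exposure, the outcome beta is
    sign-flipped.  Palindromic variants (A/T, C/G) are rejected because the
    strand cannot be resolved from alleles alone.
    """
    ea_x, oa_x = str(exposure["effect_allele"]), str(exposure["other_allele"])
    ea_y, oa_y = str(outcome["effect_allele"]), str(outcome["other_allele"])
    if drop_palindromic and (ea_x, oa_x) in _PALINDROMIC:
        raise HarmonizationError(
            f"palindromic variant {exposure['variant_id']} ({ea_x}/{oa_x}) dropped")
    if (ea_y, oa_y) == (ea_x, oa_x):
        return float(outcome["beta"]), float(outcome["se"])
    if (ea_y, oa_y) == (oa_x, ea_x):
        return -float(outcome["beta"]), float(outcome["se"])
    raise HarmonizationError(
        f"allele mismatch at {exposure['variant_id']}: "
        f"exposure {ea_x}/{oa_x} vs outcome {ea_y}/{oa_y}")


def wald_ratio(exposure: pd.DataFrame, outcome: pd.DataFrame, variant_id: str,
               protein_id: str = "", trait_id: str = "",
               alpha_mr: float = MR_ALPHA, min_beta_exp: float = 1e-8
               ) -> CausalResult:
    """Wald-ratio MR at one instrument variant.

    ``exposure``/``outcome`` are summary-stats tables containing the
    variant; alleles are harmonized first.  ``min_beta_exp`` guards against
    division by a near-zero (weak) exposure effect.
    """
    def _row(df, label):
        hit = df[df["variant_id"] == variant_id]
        if hit.empty:
            raise KeyError(f"variant {variant_id} absent from {label} stats")
        return hit.iloc[0]

    x = _row(exposure, "exposure")
    y = _row(outcome, "outcome")
    beta_out, se_out = harmonize(x, y)
    beta_exp = float(x["beta"])
    if abs(beta_exp) < min_beta_exp:
        raise ValueError(f"weak instrument: |beta_exposure| < {min_beta_exp}")
    b = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    p = float(2.0 * stats.norm.sf(abs(b) / se)) if se > 0 else 0.0
    return CausalResult(
        protein_id=protein_id, trait_id=trait_id, instrument=variant_id,
        wald_beta=b, wald_se=se, wald_p=p, mr_significant=p < alpha_mr,
    )


def _log_abf(beta: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor per variant."""
    v = se ** 2
    w = prior_sd ** 2
    r = w / (v + w)
    z2 = (beta / se) ** 2
    return 0.5 * (np.log1p(-r) + z2 * r)


def coloc_abf(stats_a: pd.DataFrame, stats_b: pd.DataFrame,
              p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
              prior_sd: float = 0.15, pp4_min: float = 0.7,
              regional_min: float = 0.6) -> dict:
    """Two-trait colocalization posteriors over one region.

    ``stats_a``/``stats_b`` are summary-stats tables for the region; only
    variants present in both (matched by ``variant_id``) enter.  Returns a
    dict with ``pp`` (PP0..PP4), ``colocalized`` (PP4 ≥ ``pp4_min`` and
    regional association ≥ ``regional_min``), ``n_variants``.
    """
    merged = stats_a.merge(stats_b, on="variant_id", suffixes=("_a", "_b"))
    if len(merged) < 2:
        raise ValueError("colocalization requires >=2 overlapping variants")
    la = _log_abf(merged["beta_a"].to_numpy(), merged["se_a"].to_numpy(), prior_sd)
    lb = _log_abf(merged["beta_b"].to_numpy(), merged["se_b"].to_numpy(), prior_sd)

    sum_a = logsumexp(la)
    sum_b = logsumexp(lb)
    sum_ab = logsumexp(la + lb)
    # H3 sums ABF_a[i]*ABF_b[j] over distinct pairs i != j:
    # log(sum_i sum_j) = sum_a + sum_b, minus the diagonal sum_ab
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = sum_a + sum_b + np.log1p(-np.exp(sum_ab - (sum_a + sum_b)))
    sum_h3 = diff if np.isfinite(diff) else -np.inf

    log_post = np.array([
        0.0,
        np.log(p1) + sum_a,
        np.log(p2) + sum_b,
        np.log(p1) + np.log(p2) + sum_h3,
        np.log(p12) + sum_ab,
    ])
    pp = np.exp(log_post - logsumexp(log_post))
    regional = 1.0 - pp[0] - pp[3]
    return {
        "pp": pp,
        "colocalized": bool(pp[4] >= pp4_min and regional >= regional_min),
        "n_variants": len(merged),
        "regional": float(regional),
    }
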