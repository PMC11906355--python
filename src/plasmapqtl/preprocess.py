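"""Matrix filtering, missing-value imputation and normalization.

The proteomics matrices enter on the log2 scale.  The preprocessing chain
is: completeness filter (keep features with ≥60% valid values) →
downshifted-normal imputation of the remaining missing cells → rank-based
inverse normal transformation (INT) → covariate residualization → re-INT.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BLOM_OFFSET",
    "filter_completeness",
    "impute_downshifted",
    "inverse_normal_transform",
    "int_matrix",
    "residualize",
    "GWAS_COVARIATES",
]

#: Blom offset c of the rank-based inverse normal transformation
BLOM_OFFSET = 3.0 / 8.0

#: covariates removed from protein levels before genetic association:
#: age, sex, BMI-SDS, obesity, obesity x BMI-SDS, PC1 and storage time
GWAS_COVARIATES = ["age", "sex", "bmi_sds", "obesity", "obesity_x_bmi_sds",
                   "storage", "pc1"]


def filter_completeness(matrix: pd.DataFrame, min_valid_fraction: float = 0.6):
    """Keep features (columns) with at least ``min_valid_fraction`` valid values.

    The boundary is inclusive: a feature with exactly 60% valid values in a
    cohort is retained.  Returns ``(filtered matrix, list of dropped
    feature ids)``; column order is preserved.
    """
    if not (0.0 < min_valid_fraction <= 1.0):
        raise ValueError("min_valid_fraction must lie in (0, 1]")
    frac = matrix.notna().mean(axis=0)
    keep = frac >= min_valid_fraction
    dropped = list(matrix.columns[~keep])
    out = matrix.loc[:, keep]
    if out.shape[1] == 0:
        import warnings
        warnings.warn("completeness filter removed every feature", stacklevel=2)
    return out, dropped


def impute_downshifted(matrix: pd.DataFrame, shift: float = 1.8,
                       width: float = 0.3, seed: int | np.random.Generator = 0
                       ) -> pd.DataFrame:
    """Impute missing log2 intensities from a downshifted normal.

    For each sample (row) with observed mean μ_s and SD σ_s across features,
    missing cells are drawn from Normal(μ_s − shift·σ_s, (width·σ_s)²) —
    mimicking values below the detection limit.  Observed cells are never
    touched.  Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = matrix.to_numpy(dtype=float).copy()
    n_obs = np.sum(np.isfinite(vals), axis=1)
    if np.any(n_obs < 2):
        bad = list(matrix.index[n_obs < 2])
        raise ValueError(f"samples with <2 observed values (SD undefined): {bad[:5]}")
    mu = np.nanmean(vals, axis=1)
    sd = np.nanstd(vals, axis=1, ddof=1)
    miss = ~np.isfinite(vals)
    draws = rng.normal(0.0, 1.0, size=vals.shape)
    filled = (mu - shift * sd)[:, None] + (width * sd)[:, None] * draws
    vals[miss] = filled[miss]
    return pd.DataFrame(vals, index=matrix.index, columns=matrix.columns)


def inverse_normal_transform(values, c: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transformation with Blom offset.

    Maps the observation of rank r_i among N non-missing values to
    Φ⁻¹((r_i − c) / (N − 2c + 1)).  Missing values stay missing and are
    excluded from N.  Ties receive average ranks, so the transform is
    deterministic and rank-preserving.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    obs = np.isfinite(x)
    n = int(obs.sum())
    if n == 0:
        raise ValueError("inverse_normal_transform requires >=1 non-missing value")
    ranks = stats.rankdata(x[obs], method="average")
    out[obs] = stats.norm.ppf((ranks - c) / (n - 2.0 * c + 1.0))
    return out


def int_matrix(matrix: pd.DataFrame, c: float = BLOM_OFFSET) -> pd.DataFrame:
    """Apply the INT column-wise (each feature transformed independently)."""
    out = {col: inverse_normal_transform(matrix[col].to_numpy(), c=c)
           for col in matrix.columns}
    return pd.DataFrame(out, index=matrix.index)[matrix.columns]


def _design(covariates: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Covariate design with derived interaction columns and intercept."""
    X = pd.DataFrame(index=covariates.index)
    for t in terms:
        if t == "obesity_x_bmi_sds":
            X[t] = covariates["obesity"] * covariates["bmi_sds"]
        else:
            X[t] = covariates[t]
    X.insert(0, "const", 1.0)
    return X


def residualize(matrix: pd.DataFrame, covariates: pd.DataFrame,
                terms: list[str] | None = None, re_int: bool = True,
                c: float = BLOM_OFFSET) -> pd.DataFrame:
    """Residualize INT-transformed features on covariates, then re-INT.

    Per feature: OLS residuals of INT(feature) on the covariate design;
    samples with missing covariates are dropped (complete-case).  If
    ``re_int`` the residuals are standardized again by the INT, which is
    the phenotype used for genetic association testing.
    """
    terms = GWAS_COVARIATES if terms is None else terms
    X = _design(covariates, terms)
    complete = X.notna().all(axis=1)
    X = X.loc[complete]
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # identify a collinear column by testing each against the rest
        bad = []
        for j in range(1, Xv.shape[1]):
            others = np.delete(Xv, j, axis=1)
            proj, *_ = np.linalg.lstsq(others, Xv[:, j], rcond=None)
            if np.allclose(others @ proj, Xv[:, j], atol=1e-8):
                bad.append(X.columns[j])
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")

    sub = matrix.loc[complete]
    out = np.full(sub.shape, np.nan)
    vals = int_matrix(sub, c=c).to_numpy(dtype=float)
    for j in range(vals.shape[1]):
        y = vals[:, j]
        obs = np.isfinite(y)
        beta, *_ = np.linalg.lstsq(Xv[obs], y[obs], rcond=None)
        out[obs, j] = y[obs] - Xv[obs] @ beta
    res = pd.DataFrame(out, index=sub.index, columns=sub.columns)
    if re_int:
        res = int_matrix(res, c=c)
    return res
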