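"""Association of protein levels with age, sex, BMI-SDS and obesity.

Per protein, an OLS multiple regression of the INT-transformed level on
age, sex, BMI-SDS, obesity status, the obesity × BMI-SDS interaction,
pubertal status, plasma storage time and PC1 (optionally plus age×BMI-SDS,
sex×BMI-SDS and age×sex interactions).  Coefficients are tested with
two-sided t tests and corrected across proteins per term by
Benjamini–Hochberg.  Sex is coded female = 1, male = 0; obesity is 1 for
the obesity-clinic group.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .io_formats import CohortBundle

__all__ = ["PhenoAssociation", "fit_pheno_model", "bh_adjust", "diagnostics",
           "BASE_TERMS", "EXTRA_INTERACTIONS"]

BASE_TERMS = ["age", "sex", "bmi_sds", "obesity", "obesity_x_bmi_sds",
              "puberty", "storage", "pc1"]
EXTRA_INTERACTIONS = ["age_x_bmi_sds", "sex_x_bmi_sds", "age_x_sex"]


@dataclasses.dataclass
class PhenoAssociation:
    """One (protein, model term) association."""

    protein_id: str
    term: str
    beta: float
    se: float
    p: float
    p_adj: float
    n: int


def _design(cov: pd.DataFrame, extra_interactions: bool) -> pd.DataFrame:
    X = pd.DataFrame(index=cov.index)
    X["age"] = cov["age"]
    X["sex"] = cov["sex"]
    X["bmi_sds"] = cov["bmi_sds"]
    X["obesity"] = cov["obesity"]
    X["obesity_x_bmi_sds"] = cov["obesity"] * cov["bmi_sds"]
    X["puberty"] = cov["puberty"]
    X["storage"] = cov["storage"]
    X["pc1"] = cov["pc1"]
    if extra_interactions:
        X["age_x_bmi_sds"] = cov["age"] * cov["bmi_sds"]
        X["sex_x_bmi_sds"] = cov["sex"] * cov["bmi_sds"]
        X["age_x_sex"] = cov["age"] * cov["sex"]
    return sm.add_constant(X)


def fit_pheno_model(bundle: CohortBundle, extra_interactions: bool = False,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Fit the demographic model for every protein (complete-case).

    Input protein levels are INT-transformed internally if the caller has
    not already done so is NOT assumed — pass the INT matrix.  Returns a
    tidy DataFrame with one row per (protein, term); ``p_adj`` is the BH
    adjustment across proteins within each term, and ``significant`` flags
    ``p_adj < alpha``.  Proteins whose design is singular are recorded with
    NaN estimates and the run continues.
    """
    X = _design(bundle.covariates, extra_interactions)
    complete = X.notna().all(axis=1)
    X = X.loc[complete]
    prot = bundle.proteins.loc[complete]
    terms = [c for c in X.columns if c != "const"]

    rows = []
    for pid in prot.columns:
        y = prot[pid]
        obs = y.notna()
        try:
            fit = sm.OLS(y[obs], X.loc[obs]).fit()
            if fit.df_resid < 1 or np.linalg.matrix_rank(X.loc[obs]) < X.shape[1]:
                raise np.linalg.LinAlgError("singular design")
            for t in terms:
                rows.append((pid, t, fit.params[t], fit.bse[t],
                             float(fit.pvalues[t]), int(obs.sum()), False))
        except (np.linalg.LinAlgError, ValueError):
            for t in terms:
                rows.append((pid, t, np.nan, np.nan, np.nan, int(obs.sum()), True))

    out = pd.DataFrame(rows, columns=["protein_id", "term", "beta", "se", "p",
                                      "n", "failed"])
    out["p_adj"] = np.nan
    for t in terms:
        mask = (out["term"] == t) & out["p"].notna()
        if mask.any():
            out.loc[mask, "p_adj"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def diagnostics(bundle: CohortBundle, extra_interactions: bool = False
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model diagnostics: predictor VIFs and per-protein residual normality.

    VIF_j = 1 / (1 − R²) of predictor j regressed on the other predictors;
    values above 10 indicate serious multicollinearity.  Residual normality
    uses the Shapiro–Wilk test per protein.  Returns ``(vif_table,
    normality_table)``; the normality table carries the fraction of
    proteins with P > 0.05 in its ``.attrs['fraction_normal']``.
    """
    X = _design(bundle.covariates, extra_interactions)
    complete = X.notna().all(axis=1)
    X = X.loc[complete]
    terms = [c for c in X.columns if c != "const"]
    Xv = X.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        vifs = [variance_inflation_factor(Xv, X.columns.get_loc(t)) for t in terms]
    vif_table = pd.DataFrame({"predictor": terms, "vif": vifs})

    prot = bundle.proteins.loc[complete]
    rows = []
    for pid in prot.columns:
        y = prot[pid]
        obs = y.notna()
        beta, *_ = np.linalg.lstsq(Xv[obs.to_numpy()], y[obs].to_numpy(), rcond=None)
        resid = y[obs].to_numpy() - Xv[obs.to_numpy()] @ beta
        if resid.size >= 3:
            w, p_norm = stats.shapiro(resid)
        else:
            w, p_norm = np.nan, np.nan
        rows.append((pid, w, p_norm))
    norm_table = pd.DataFrame(rows, columns=["protein_id", "shapiro_w", "p_normal"])
    norm_table.attrs["fraction_normal"] = float((norm_table["p_normal"] > 0.05).mean())
    return vif_table, norm_table
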