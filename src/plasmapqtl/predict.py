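"""Age and BMI prediction from plasma protein levels.

Protocol: the cohort is split 70/30 into training and held-out test sets;
the training set is split again 70/30 into an inner training and validation
set.  Features (proteins) are ranked by absolute Pearson correlation with
the outcome on the inner training set only; OLS models with the top
k = 1..200 features are scored on the validation set, k is chosen as the
smallest value whose validation MSE is within 1% of the curve minimum
(a parsimony-preserving reading of "incremental decrease"), the model is
refit on the full training set and evaluated once on the test set.
Ranking and selection never see test samples.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import train_test_split

__all__ = ["PredictionReport", "train_predictor"]


@dataclasses.dataclass
class PredictionReport:
    """Feature-selection trace and held-out performance for one outcome."""

    outcome: str
    selected_features: list[str]   # in selection (ranking) order
    k_selected: int
    mse_curve: np.ndarray          # validation MSE over k = 1..k_max
    test_mae: float
    test_r: float
    n_train: int
    n_test: int


def train_predictor(features: pd.DataFrame, outcome: pd.Series,
                    outcome_name: str = "age", k_max: int = 200,
                    split: float = 0.3, inner_split: float = 0.3,
                    seed: int = 0, mse_tolerance: float = 0.01
                    ) -> PredictionReport:
    """Run the ranking + incremental-feature-selection protocol.

    ``features`` is the (complete, e.g. imputed) sample × protein matrix;
    samples with a missing outcome are dropped.  ``k_max`` is capped at the
    number of available features with a warning.
    """
    keep = outcome.notna()
    X = features.loc[keep]
    y = outcome.loc[keep]
    if k_max > X.shape[1]:
        import warnings
        warnings.warn(f"k_max={k_max} exceeds {X.shape[1]} features; capped",
                      stacklevel=2)
        k_max = X.shape[1]

    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=split, random_state=seed)
    X_fit, X_val, y_fit, y_val = train_test_split(
        X_train, y_train, test_size=inner_split, random_state=seed + 1)

    # rank features on the inner training set only
    xc = X_fit.to_numpy(dtype=float)
    yc = y_fit.to_numpy(dtype=float)
    xs = (xc - xc.mean(axis=0)) / xc.std(axis=0, ddof=0)
    ys = (yc - yc.mean()) / yc.std(ddof=0)
    corr = np.abs(xs.T @ ys) / len(ys)
    order = np.argsort(-corr, kind="stable")
    ranked = [X.columns[j] for j in order]

    mse_curve = np.empty(k_max)
    for k in range(1, k_max + 1):
        cols = ranked[:k]
        model = LinearRegression().fit(X_fit[cols], y_fit)
        pred = model.predict(X_val[cols])
        mse_curve[k - 1] = float(np.mean((pred - y_val) ** 2))

    # smallest k within 1% of the minimum validation MSE; the absolute term
    # keeps the rule stable when the fit is (near-)exact and the curve ~ 0
    best = float(mse_curve.min())
    slack = best * mse_tolerance + 1e-12 * float(np.var(y_val.to_numpy()))
    within = np.flatnonzero(mse_curve <= best + slack)
    k_selected = int(within[0]) + 1

    cols = ranked[:k_selected]
    final = LinearRegression().fit(X_train[cols], y_train)
    pred = final.predict(X_test[cols])
    test_mae = float(np.mean(np.abs(pred - y_test)))
    test_r = float(stats.pearsonr(pred, y_test)[0]) if len(y_test) > 2 else np.nan

    return PredictionReport(
        outcome=outcome_name, selected_features=cols, k_selected=k_selected,
        mse_curve=mse_curve, test_mae=test_mae, test_r=test_r,
        n_train=len(y_train), n_test=len(y_test),
    )
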