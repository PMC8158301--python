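"""Ridge-regression IC50 prediction from cell-line training expression.

The penalty is chosen by k-fold cross-validated squared error, with feature
standardization refit inside every training fold; the final model is refit
on the full training set and applied to tumor samples after projecting onto
the training gene space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold


class DrugResponseError(ValueError):
    pass


DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 3, 21))


@dataclass
class RidgeModel:
    genes: list[str]
    coefficients: np.ndarray     # on the standardized-feature scale
    intercept: float
    lambda_: float
    cv_errors: pd.Series         # lambda -> mean CV squared error
    feature_means: np.ndarray
    feature_sds: np.ndarray

    def predict(self, tumor_expr: pd.DataFrame) -> pd.Series:
        return predict_ic50(self, tumor_expr)


def ridge_train(
    cell_expr: pd.DataFrame,
    ic50: pd.Series,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    folds: int = 10,
    seed: int = 0,
) -> RidgeModel:
    """Train a ridge IC50 model with CV-selected penalty.

    ``cell_expr`` is genes x cell-lines; ``ic50`` maps cell line to response.
    """
    lambda_grid = tuple(float(v) for v in lambda_grid)
    if not lambda_grid:
        raise DrugResponseError("lambda grid is empty")
    if any(v <= 0 for v in lambda_grid):
        raise DrugResponseError("lambda grid values must be positive")
    missing = [c for c in cell_expr.columns if c not in ic50.index]
    if missing:
        raise DrugResponseError(f"cell lines without IC50: {missing[:10]}")
    y = ic50.loc[cell_expr.columns].to_numpy(dtype=float)
    x = cell_expr.to_numpy(dtype=float).T  # cell lines x genes
    n = x.shape[0]
    if n < folds:
        raise DrugResponseError(f"{n} cell lines cannot support {folds}-fold CV")

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(x))
    cv_err = {}
    for lam in lambda_grid:
        errs = []
        for train_idx, test_idx in splits:
            mu = x[train_idx].mean(axis=0)
            sd = x[train_idx].std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            model = Ridge(alpha=lam)
            model.fit((x[train_idx] - mu) / sd, y[train_idx])
            pred = model.predict((x[test_idx] - mu) / sd)
            errs.append(float(np.mean((pred - y[test_idx]) ** 2)))
        cv_err[lam] = float(np.mean(errs))
    cv_series = pd.Series(cv_err, name="cv_mse")
    best = float(cv_series.idxmin())

    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    final = Ridge(alpha=best)
    final.fit((x - mu) / sd, y)
    return RidgeModel(
        genes=[str(g) for g in cell_expr.index],
        coefficients=np.asarray(final.coef_, dtype=float),
        intercept=float(final.intercept_),
        lambda_=best,
        cv_errors=cv_series,
        feature_means=mu,
        feature_sds=sd,
    )


def predict_ic50(model: RidgeModel, tumor_expr: pd.DataFrame) -> pd.Series:
    """Apply the trained linear model to tumor samples (genes x samples)."""
    missing = [g for g in model.genes if g not in tumor_expr.index]
    if missing:
        raise DrugResponseError(f"tumor matrix is missing model genes: {missing[:10]}")
    x = tumor_expr.loc[model.genes].to_numpy(dtype=float).T
    z = (x - model.feature_means) / model.feature_sds
    pred = z @ model.coefficients + model.intercept
    return pd.Series(pred, index=tumor_expr.columns, name="predicted_ic50")
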