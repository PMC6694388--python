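"""Five-fold cross-validated model comparison.

For each fold, variable selection (for individual-code schemes) and GLM
training use only the k-1 training folds; RMSE is measured on the held-out
fold. The full-cohort pseudo R-squared comes from a separate
selection-plus-fit on the whole cohort, matching how the headline table
pairs an in-sample discrimination measure with an out-of-sample error.

Folds are assigned by admission. The candidate-frequency filter is part of
design construction and is computed once on the cohort; within-fold work
is the penalized selection and the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import DesignMatrix, Scheme, build_design
from .glm import FittedGLM, GLMSpec, fit_glm, predict, pseudo_r2, rmse
from .selection import lasso_select
from .simulate import ClaimsBundle

__all__ = ["CVResult", "cross_validate", "make_folds"]


@dataclass
class CVResult:
    """Cross-validated comparison metrics for one (scheme, spec) pair."""

    pseudo_r2_full: float
    rmse_folds: list[float]
    rmse_mean: float
    rmse_sd: float
    folds: list[np.ndarray]
    full_fit: FittedGLM
    selected_full: list[str] | None = None


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Disjoint folds of row positions covering range(n) exactly once."""
    if n < k:
        raise ValueError(f"cannot split {n} rows into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [np.sort(f) for f in np.array_split(perm, k)]
    if any(len(f) == 0 for f in folds):
        raise ValueError("fold with zero test rows")
    return folds


def _fit_with_selection(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: GLMSpec,
    design: DesignMatrix,
    select: bool,
    max_vars: int,
    alpha: float,
) -> tuple[FittedGLM, list[str] | None]:
    if select:
        res = lasso_select(
            X, y, spec, max_vars=max_vars, alpha=alpha, forced=design.forced
        )
        return res.fit, res.selected
    # drop empty and exactly duplicated indicator columns (can arise in
    # small training folds) so the unpenalized fit stays full rank
    sub = X.loc[:, X.to_numpy().any(axis=0)]
    sub = sub.loc[:, ~sub.T.duplicated()]
    return fit_glm(sub, y, spec), None


def cross_validate(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    scheme: Scheme,
    spec: GLMSpec,
    k: int = 5,
    seed: int = 0,
    select: bool | None = None,
    max_vars: int = 200,
    alpha: float = 0.005,
) -> CVResult:
    """k-fold CV of one covariate scheme under one GLM spec.

    ``select`` defaults to True for individual-code schemes (the only ones
    the study ran through LASSO) and False for grouped-category schemes.
    Deterministic given ``seed``.
    """
    if select is None:
        select = scheme.unit == "code"
    design = build_design(cohort, bundle, scheme)
    X = design.X.astype(float)
    y = cohort["payment_w"].to_numpy(dtype=float)
    folds = make_folds(len(cohort), k, seed)

    rmses: list[float] = []
    for test_idx in folds:
        train_mask = np.ones(len(cohort), dtype=bool)
        train_mask[test_idx] = False
        fit, _ = _fit_with_selection(
            X.iloc[train_mask.nonzero()[0]], y[train_mask], spec, design,
            select, max_vars, alpha,
        )
        pred = predict(fit, X.iloc[test_idx])
        rmses.append(rmse(pred, y[test_idx]))

    full_fit, selected = _fit_with_selection(
        X, y, spec, design, select, max_vars, alpha
    )
    return CVResult(
        pseudo_r2_full=pseudo_r2(full_fit),
        rmse_folds=rmses,
        rmse_mean=float(np.mean(rmses)),
        rmse_sd=float(np.std(rmses, ddof=1)),
        folds=folds,
        full_fit=full_fit,
        selected_full=selected,
    )
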