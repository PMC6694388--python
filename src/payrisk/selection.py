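"""Penalized variable selection for the individual-code models.

The selection procedure mirrors the published pipeline: an L1-penalized
path is computed for the same family/link as the final model, the smallest
penalty whose active set holds at most ``max_vars`` variables is taken,
the active set is refit as an ordinary (unpenalized) GLM, and variables
are then pruned backward until every survivor is significant at the
two-sided Wald ``P < alpha`` level. Age-band columns are forced: never
penalized, never pruned.

The path is computed by cyclic coordinate descent on the IRLS working
response with warm starts along a log-spaced penalty grid. The descent
runs on the Gram matrix of the (internally standardized) design, so a
coordinate update costs O(p) rather than O(n); for the Gamma/log family
the IRLS weights are constant and the Gram is built once for the whole
path. Coefficients are reported on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import (
    FittedGLM, GLMSpec, _as_matrix, _linkinv, _mu_eta, _start_beta,
    _variance, fit_glm,
)

__all__ = ["SelectionResult", "lasso_select"]


@dataclass
class SelectionResult:
    """Outcome of penalized selection plus the significance pruning."""

    selected: list[str]
    forced: list[str]
    chosen_lambda: float
    path: pd.DataFrame           # columns: lam, nnz
    pruning_log: list[tuple[str, float]] = field(default_factory=list)
    fit: FittedGLM | None = None


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _cd_gram(
    G: np.ndarray,
    q: np.ndarray,
    beta: np.ndarray,
    penalty: np.ndarray,
    max_passes: int = 1000,
    tol: float = 1e-6,
) -> np.ndarray:
    """Coordinate descent for 0.5 b'Gb - q'b + sum(pen_j |b_j|).

    ``G = X'WX`` and ``q = X'Wz`` of the weighted working-response
    least-squares problem. Maintains s = G beta incrementally, so each
    coordinate update is O(p).
    """
    p = len(q)
    diag = np.diag(G).copy()
    diag[diag == 0] = 1.0
    s = G @ beta
    active = np.flatnonzero((beta != 0.0) | (penalty == 0.0))
    for _round in range(max_passes):
        for _sweep in range(max_passes):
            max_delta = 0.0
            for j in active:
                bj = beta[j]
                rho = q[j] - s[j] + diag[j] * bj
                bnew = _soft(rho, penalty[j]) / diag[j]
                if bnew != bj:
                    s += G[:, j] * (bnew - bj)
                    beta[j] = bnew
                    max_delta = max(max_delta, abs(bnew - bj))
            if max_delta < tol * max(1.0, float(np.max(np.abs(beta)))):
                break
        # KKT check over all coordinates is O(p) with s maintained
        rho_all = q - s + diag * beta
        viol = np.flatnonzero(
            (beta == 0.0)
            & (np.abs(rho_all) > penalty * (1 + 1e-9) + 1e-9)
        )
        viol = np.setdiff1d(viol, active, assume_unique=False)
        if viol.size == 0:
            break
        active = np.concatenate([active, viol])
    return beta


def _irls_quantities(M, y, beta, spec):
    eta = M @ beta
    mu = _linkinv(eta, spec.link)
    dmu = _mu_eta(eta, spec.link)
    w = dmu ** 2 / _variance(mu, spec.family)
    z = eta + (y - mu) / dmu
    return eta, mu, w, z


def _weights_constant(spec: GLMSpec) -> bool:
    # Gamma variance mu^2 with log link: w = (dmu/deta)^2 / V(mu) = 1
    return spec.family == "gamma" and spec.link == "log"


def _penalized_irls(
    M: np.ndarray,
    y: np.ndarray,
    spec: GLMSpec,
    penalty: np.ndarray,
    beta0: np.ndarray,
    gram_cache: dict,
    max_iter: int = 15,
    tol: float = 1e-5,
) -> np.ndarray:
    beta = beta0.copy()
    eta = M @ beta
    mu = _linkinv(eta, spec.link)
    if (mu <= 0).any():
        beta = np.zeros_like(beta)
        beta[0] = _start_beta(M, y, spec.link)[0]
    const_w = _weights_constant(spec)
    for _ in range(max_iter):
        eta, mu, w, z = _irls_quantities(M, y, beta, spec)
        if const_w and "G" in gram_cache:
            G = gram_cache["G"]
            q = M.T @ z
        else:
            Mw = M * w[:, None]
            G = Mw.T @ M
            q = Mw.T @ z
            if const_w:
                gram_cache["G"] = G
        beta_old = beta.copy()
        beta = _cd_gram(G, q, beta, penalty)
        # step-halve toward the previous iterate if the mean leaves (0, inf)
        eta_new = M @ beta
        mu_new = _linkinv(eta_new, spec.link)
        lam = 1.0
        while ((mu_new <= 0).any() or not np.isfinite(mu_new).all()) and lam > 1e-8:
            lam *= 0.5
            beta = beta_old + lam * (beta - beta_old)
            eta_new = M @ beta
            mu_new = _linkinv(eta_new, spec.link)
        if np.max(np.abs(beta - beta_old)) < tol * max(1.0, np.max(np.abs(beta))):
            break
    return beta


def lasso_select(
    X: pd.DataFrame,
    y,
    spec: GLMSpec,
    max_vars: int = 200,
    alpha: float = 0.005,
    forced: tuple[str, ...] = ("age_75_84", "age_85p"),
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    refit: bool = True,
) -> SelectionResult:
    """Select at most ``max_vars`` candidate columns; prune to P < alpha.

    ``forced`` columns (and the intercept) are never penalized and survive
    regardless of significance. Returns the selection, the penalty-path
    metadata, the pruning log and (when ``refit``) the final unpenalized
    GLM on forced + selected columns.
    """
    y = np.asarray(y, dtype=float)
    forced = tuple(c for c in forced if c in X.columns)
    candidates = [c for c in X.columns if c not in forced]
    # drop empty candidate columns up front
    nz = X[candidates].to_numpy().any(axis=0)
    candidates = [c for c, keep in zip(candidates, nz) if keep]

    M, _names = _as_matrix(X[list(forced) + candidates], add_const=True)
    p = M.shape[1]
    n_forced = 1 + len(forced)
    # standardize penalized columns only (in place on a copy)
    sd = np.ones(p)
    for j in range(n_forced, p):
        s = M[:, j].std()
        sd[j] = s if s > 0 else 1.0
    M = M / sd

    # lambda_max: smallest penalty zeroing all candidates, from the
    # working-response gradient at the forced-only fit
    base = fit_glm(X[list(forced)], y, spec)
    beta = np.zeros(p)
    beta[:n_forced] = base.params.to_numpy()
    _eta, _mu, w, z = _irls_quantities(M, y, beta, spec)
    grad = M[:, n_forced:].T @ (w * (z - _eta))
    lam_max = float(np.max(np.abs(grad))) if p > n_forced else 0.0
    if lam_max <= 0 or max_vars == 0 or not candidates:
        path = pd.DataFrame({"lam": [lam_max], "nnz": [0]})
        fit = base if refit else None
        return SelectionResult(
            selected=[], forced=list(forced), chosen_lambda=lam_max,
            path=path, fit=fit,
        )

    grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    penalty = np.zeros(p)
    gram_cache: dict = {}
    lams, nnzs, actives = [], [], []
    for lam in grid:
        penalty[n_forced:] = lam
        beta = _penalized_irls(M, y, spec, penalty, beta, gram_cache)
        active = np.flatnonzero(np.abs(beta[n_forced:]) > 1e-10)
        lams.append(float(lam))
        nnzs.append(len(active))
        actives.append(active)
        if len(active) > max_vars:
            break
    path = pd.DataFrame({"lam": lams, "nnz": nnzs})
    ok = [i for i, k in enumerate(nnzs) if k <= max_vars]
    i_star = ok[-1]  # smallest penalty meeting the size constraint
    selected = [candidates[j] for j in actives[i_star]]
    chosen_lambda = lams[i_star]

    pruning_log: list[tuple[str, float]] = []
    fit = None
    if refit:
        current = list(selected)
        while True:
            fit = fit_glm(X[list(forced) + current], y, spec)
            if not current:
                break
            pv = fit.pvalues[current]
            worst = pv.idxmax()
            if pv[worst] < alpha:
                break
            pruning_log.append((worst, float(pv[worst])))
            current.remove(worst)
        selected = current
    return SelectionResult(
        selected=selected, forced=list(forced), chosen_lambda=chosen_lambda,
        path=path, pruning_log=pruning_log, fit=fit,
    )
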