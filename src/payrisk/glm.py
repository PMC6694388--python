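"""GLM fitting and comparison metrics for strictly positive payments.

Three family/link pairs are supported, matching the published payment
measures: inverse Gaussian with log link (AMI), Gamma with log link (HF)
and Gamma with identity link (pneumonia). Fitting is by iteratively
reweighted least squares with step-halving, which keeps identity-link
means strictly positive — the practical failure mode of off-the-shelf
identity-link Gamma fits on payment data.

Dispersion phi is the Pearson chi-square estimate at the final fit.
McFadden's pseudo R-squared evaluates model and null log-likelihoods at
the full model's phi, so the ratio reflects mean-structure improvement
only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "GLMSpec", "FittedGLM", "DEFAULT_SPECS", "fit_glm", "loglik",
    "pseudo_r2", "rmse", "predict",
]

FAMILIES = ("gamma", "inverse_gaussian")
LINKS = ("log", "identity")


@dataclass(frozen=True)
class GLMSpec:
    """Family/link pair; only the three published pairs are accepted by
    default (set ``allow_any`` for others)."""

    family: str
    link: str
    allow_any: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}")
        pair = (self.family, self.link)
        allowed = {("inverse_gaussian", "log"), ("gamma", "log"),
                   ("gamma", "identity")}
        if pair not in allowed and not self.allow_any:
            raise ValueError(
                f"{pair} is not one of the default payment-model pairs; "
                "pass allow_any=True to opt in"
            )


DEFAULT_SPECS: Mapping[str, GLMSpec] = {
    "AMI": GLMSpec("inverse_gaussian", "log"),
    "HF": GLMSpec("gamma", "log"),
    "PN": GLMSpec("gamma", "identity"),
}


class ConvergenceError(RuntimeError):
    """IRLS failed; carries the convergence record."""

    def __init__(self, msg: str, record: dict):
        super().__init__(msg)
        self.record = record


def _variance(mu: np.ndarray, family: str) -> np.ndarray:
    return mu ** 2 if family == "gamma" else mu ** 3


def _deviance(y: np.ndarray, mu: np.ndarray, family: str) -> float:
    if family == "gamma":
        return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))
    return float(np.sum((y - mu) ** 2 / (mu ** 2 * y)))


def _linkinv(eta: np.ndarray, link: str) -> np.ndarray:
    return np.exp(eta) if link == "log" else eta


def _mu_eta(eta: np.ndarray, link: str) -> np.ndarray:
    return np.exp(eta) if link == "log" else np.ones_like(eta)


@dataclass
class FittedGLM:
    """A converged GLM fit.

    ``loglik``/``null_loglik`` are evaluated at the Pearson dispersion of
    this fit (common-dispersion convention), so the null likelihood of a
    covariate model is comparable for McFadden's pseudo R-squared.
    """

    spec: GLMSpec
    params: pd.Series
    dispersion: float
    loglik: float
    null_loglik: float
    cov_params: pd.DataFrame
    n_obs: int
    n_iter: int
    converged: bool
    deviance: float

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.values)),
                         index=self.params.index)

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        return predict(self, X)


def loglik(spec: GLMSpec, y, mu, phi: float) -> float:
    """Sum of log-densities.

    Gamma: shape 1/phi, scale phi*mu (Var = phi*mu^2).
    Inverse Gaussian: Var = phi*mu^3, i.e. lambda = 1/phi.
    """
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    if phi <= 0:
        raise ValueError("phi must be positive")
    if (y <= 0).any() or (mu <= 0).any():
        raise ValueError("y and mu must be strictly positive")
    if spec.family == "gamma":
        a = 1.0 / phi
        return float(np.sum(
            -gammaln(a) - a * np.log(phi * mu) + (a - 1.0) * np.log(y)
            - y / (phi * mu)
        ))
    return float(np.sum(
        -0.5 * np.log(2.0 * np.pi * phi * y ** 3)
        - (y - mu) ** 2 / (2.0 * phi * mu ** 2 * y)
    ))


def _as_matrix(X, add_const: bool) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        names = [f"x{i}" for i in range(M.shape[1])]
    if add_const:
        M = np.column_stack([np.ones(len(M)), M])
        names = ["const"] + names
    return M, names


def _start_beta(M: np.ndarray, y: np.ndarray, link: str) -> np.ndarray:
    beta = np.zeros(M.shape[1])
    ybar = float(np.mean(y))
    beta[0] = np.log(ybar) if link == "log" else ybar
    return beta


def _wls_solve(
    M: np.ndarray,
    w: np.ndarray,
    z: np.ndarray,
    gram_cache: dict | None,
) -> np.ndarray:
    """Weighted least squares via the normal equations.

    Rank-deficient designs (duplicate/collinear columns) surface as a
    Cholesky failure. For constant-weight families the Gram factor is
    cached across IRLS iterations.
    """
    from scipy.linalg import cho_factor, cho_solve

    if gram_cache is not None and "cho" in gram_cache:
        cho = gram_cache["cho"]
        q = M.T @ (w * z) if gram_cache.get("w_is_one") else (M * w[:, None]).T @ z
    else:
        Mw = M * w[:, None]
        G = Mw.T @ M
        q = Mw.T @ z
        try:
            cho = cho_factor(G)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                f"design matrix is rank deficient ({M.shape[1]} columns)"
            ) from e
        if gram_cache is not None:
            gram_cache["cho"] = cho
            gram_cache["w_is_one"] = bool(np.all(w == 1.0))
    return cho_solve(cho, q)


def _irls(
    M: np.ndarray,
    y: np.ndarray,
    spec: GLMSpec,
    beta0: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, bool]:
    """Return (beta, mu, working weights, iterations, converged)."""
    n, p = M.shape
    beta = _start_beta(M, y, spec.link) if beta0 is None else beta0.copy()
    eta = M @ beta
    mu = _linkinv(eta, spec.link)
    if (mu <= 0).any():
        beta = _start_beta(M, y, spec.link)
        eta = M @ beta
        mu = _linkinv(eta, spec.link)
    dev = _deviance(y, mu, spec.family)
    it = 0
    converged = False
    w = np.ones(n)
    # Gamma/log has unit working weights: one Gram factorization suffices
    gram_cache: dict | None = (
        {} if (spec.family == "gamma" and spec.link == "log") else None
    )
    for it in range(1, max_iter + 1):
        dmu = _mu_eta(eta, spec.link)
        w = dmu ** 2 / _variance(mu, spec.family)
        z = eta + (y - mu) / dmu
        beta_new = _wls_solve(M, w, z, gram_cache)
        step = beta_new - beta
        # step-halving: keep mu positive and deviance non-increasing
        lam = 1.0
        for _ in range(60):
            cand = beta + lam * step
            eta_c = M @ cand
            mu_c = _linkinv(eta_c, spec.link)
            if (mu_c > 0).all() and np.isfinite(mu_c).all():
                dev_c = _deviance(y, mu_c, spec.family)
                if dev_c <= dev * (1 + 1e-10) or lam < 1e-8:
                    break
            lam *= 0.5
        else:
            raise ConvergenceError(
                "step-halving could not restore a positive mean",
                {"iteration": it, "deviance": dev},
            )
        beta, eta, mu = cand, eta_c, mu_c
        dev_new = _deviance(y, mu, spec.family)
        if abs(dev - dev_new) <= tol * (abs(dev_new) + 0.1):
            dev = dev_new
            converged = True
            break
        dev = dev_new
    return beta, mu, w, it, converged


def fit_glm(
    X,
    y,
    spec: GLMSpec,
    add_const: bool = True,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> FittedGLM:
    """Fit a GLM by IRLS with step-halving.

    ``X`` (DataFrame or array) should not contain the intercept; a constant
    column is prepended unless ``add_const=False``. Raises on rank-deficient
    design (e.g. duplicated columns) or non-convergence.
    """
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ValueError("outcome must be strictly positive")
    M, names = _as_matrix(X, add_const)
    if len(M) != len(y):
        raise ValueError("X and y lengths differ")
    # duplicate/collinear columns surface as a rank-deficiency error from
    # the Gram factorization inside IRLS
    beta, mu, w, it, converged = _irls(M, y, spec, max_iter=max_iter, tol=tol)
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations",
            {"iterations": it, "deviance": _deviance(y, mu, spec.family)},
        )
    n, p = M.shape
    pearson = float(np.sum((y - mu) ** 2 / _variance(mu, spec.family)))
    phi = pearson / max(n - p, 1)
    ll = loglik(spec, y, mu, phi)
    ll0 = loglik(spec, y, float(np.mean(y)), phi)  # intercept-only MLE mean
    XtWX = (M * w[:, None]).T @ M
    cov = phi * np.linalg.inv(XtWX)
    return FittedGLM(
        spec=spec,
        params=pd.Series(beta, index=names),
        dispersion=phi,
        loglik=ll,
        null_loglik=ll0,
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        n_obs=n,
        n_iter=it,
        converged=converged,
        deviance=_deviance(y, mu, spec.family),
    )


def predict(fit: FittedGLM, X) -> np.ndarray:
    """Mean payment on the response scale for new rows."""
    if isinstance(X, pd.DataFrame):
        feats = [c for c in fit.params.index if c != "const"]
        M = X.reindex(columns=feats, fill_value=0.0).to_numpy(dtype=float)
        eta = M @ fit.params[feats].to_numpy()
    else:
        M, _ = _as_matrix(X, add_const=False)
        eta = M @ fit.params.to_numpy()[1:]
    if "const" in fit.params.index:
        eta = eta + fit.params["const"]
    return _linkinv(eta, fit.spec.link)


def pseudo_r2(fit: FittedGLM) -> float:
    """McFadden's pseudo R-squared, 1 - loglik/null_loglik, clipped to
    [0, 1]; both likelihoods share the fit's dispersion."""
    if fit.null_loglik == 0:
        raise ZeroDivisionError("null log-likelihood is zero")
    return float(np.clip(1.0 - fit.loglik / fit.null_loglik, 0.0, 1.0))


def rmse(pred, actual) -> float:
    """Root mean squared prediction error, in dollars."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("pred and actual lengths differ")
    if pred.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((pred - actual) ** 2)))
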