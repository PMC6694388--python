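"""Hospital payment profiling: hierarchical GLM, risk-standardized
payments, cluster-bootstrap confidence intervals and 3-way categorization.

The model is a random-intercept GLM on the link scale,
g(mu_ij) = x_ij'beta + alpha_i with alpha_i ~ Normal(0, tau^2) per
hospital. Estimation alternates IRLS updates of beta with closed-form
shrinkage of the hospital intercepts given tau, and a method-of-moments
update of tau^2 (the dispersion of the raw per-hospital intercepts minus
their average sampling variance) — the standard
penalized-quasi-likelihood-style estimator for profiling models.

The risk-standardized payment (RSP) for hospital i is
(predicted / expected) x national mean, where "predicted" sums
g^-1(x'beta + alpha_i) over the hospital's cases and "expected" sets the
random effect to its prior mean of zero (an average hospital with the
same case mix). Under a log link the ratio reduces to exp(alpha_i)
exactly, independent of case mix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import (
    ConvergenceError, GLMSpec, _as_matrix, _linkinv, _mu_eta, _variance,
    fit_glm,
)

__all__ = [
    "HierFit", "CategoryShiftTable", "fit_hierarchical", "rsp",
    "bootstrap_ci", "categorize", "shift_table", "shift_table_from_counts",
    "infer_extreme_shifts", "profile_hospitals",
]

CATEGORIES = ("lower", "no_different", "higher")


@dataclass
class HierFit:
    """Converged random-intercept GLM."""

    spec: GLMSpec
    beta: pd.Series
    alpha: pd.Series          # shrunken hospital intercepts, link scale
    tau: float                # random-effect SD on the link scale
    dispersion: float
    n_iter: int
    converged: bool


def fit_hierarchical(
    X,
    y,
    hospital_ids,
    spec: GLMSpec,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> HierFit:
    """Fit g(mu) = x'beta + alpha_hospital with shrunken hospital effects.

    Requires at least two hospitals and strictly positive outcomes. The
    returned ``alpha`` is centered (its weighted mean is absorbed into the
    intercept) and shrunk toward zero by tau^2 / (tau^2 + sampling var).
    """
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ValueError("outcome must be strictly positive")
    hospital_ids = np.asarray(hospital_ids)
    hosp, hidx = np.unique(hospital_ids, return_inverse=True)
    H = len(hosp)
    if H < 2:
        raise ValueError("hierarchical fit needs at least 2 hospitals")
    M, names = _as_matrix(X, add_const=True)

    flat = fit_glm(X, y, spec)
    beta = flat.params.to_numpy().copy()
    alpha = np.zeros(H)
    tau2 = 0.0
    phi = flat.dispersion
    for it in range(1, max_iter + 1):
        eta = M @ beta + alpha[hidx]
        mu = _linkinv(eta, spec.link)
        if (mu <= 0).any():
            raise ConvergenceError(
                "hierarchical fit produced non-positive means",
                {"iteration": it},
            )
        dmu = _mu_eta(eta, spec.link)
        w = dmu ** 2 / _variance(mu, spec.family)
        z = eta + (y - mu) / dmu
        phi = float(
            np.sum((y - mu) ** 2 / _variance(mu, spec.family))
            / max(len(y) - M.shape[1], 1)
        )
        # raw per-hospital intercepts of the working residual
        r = z - M @ beta
        sw = np.bincount(hidx, weights=w, minlength=H)
        swr = np.bincount(hidx, weights=w * r, minlength=H)
        a = swr / sw
        v = phi / sw
        abar = float(np.sum(sw * a) / np.sum(sw))
        a = a - abar
        tau2_new = max(0.0, float(np.var(a, ddof=1) - np.mean(v)))
        alpha_new = a * tau2_new / (tau2_new + v) if tau2_new > 0 else np.zeros(H)
        # beta given alpha: weighted least squares on the offset-adjusted
        # working response (the centering shift folds into the intercept)
        sqw = np.sqrt(w)
        target = z - alpha_new[hidx]
        beta_new, *_ = np.linalg.lstsq(M * sqw[:, None], target * sqw, rcond=None)
        delta = max(
            float(np.max(np.abs(beta_new - beta))),
            float(np.max(np.abs(alpha_new - alpha))),
            abs(tau2_new - tau2),
        )
        beta, alpha, tau2 = beta_new, alpha_new, tau2_new
        if delta < tol * max(1.0, float(np.max(np.abs(beta)))):
            return HierFit(
                spec=spec,
                beta=pd.Series(beta, index=names),
                alpha=pd.Series(alpha, index=hosp, name="alpha"),
                tau=float(np.sqrt(tau2)),
                dispersion=phi,
                n_iter=it,
                converged=True,
            )
    raise ConvergenceError(
        f"hierarchical IRLS did not converge in {max_iter} iterations",
        {"iterations": max_iter, "tau2": tau2},
    )


def rsp(
    fit: HierFit,
    X,
    hospital_ids,
    national_mean: float,
) -> pd.DataFrame:
    """Per-hospital predicted/expected totals and risk-standardized payment.

    predicted P_i = sum_j g^-1(x_j'beta + alpha_i) over hospital i's cases;
    expected  E_i = sum_j g^-1(x_j'beta);
    RSP_i = (P_i / E_i) x national_mean.
    """
    if national_mean <= 0:
        raise ValueError("national_mean must be positive")
    hospital_ids = np.asarray(hospital_ids)
    M, _ = _as_matrix(X, add_const=True)
    hosp, hidx = np.unique(hospital_ids, return_inverse=True)
    alpha = fit.alpha.reindex(hosp).to_numpy()
    if np.isnan(alpha).any():
        raise ValueError("hospital_ids outside the fitted hospital set")
    eta0 = M @ fit.beta.to_numpy()
    pred = _linkinv(eta0 + alpha[hidx], fit.spec.link)
    expd = _linkinv(eta0, fit.spec.link)
    H = len(hosp)
    P = np.bincount(hidx, weights=pred, minlength=H)
    E = np.bincount(hidx, weights=expd, minlength=H)
    if (E <= 0).any() or (P <= 0).any():
        raise ValueError("non-positive predicted/expected totals")
    return pd.DataFrame({
        "hospital_id": hosp,
        "n_cases": np.bincount(hidx, minlength=H),
        "predicted": P,
        "expected": E,
        "rsp": P / E * national_mean,
    }).set_index("hospital_id")


def bootstrap_ci(
    X: pd.DataFrame,
    y,
    hospital_ids,
    spec: GLMSpec,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Cluster-bootstrap percentile CIs for each hospital's RSP.

    Hospitals are resampled with replacement; the hierarchical model and
    the national mean are recomputed per replicate; each original hospital
    collects the RSP of every replicate copy of itself. Deterministic given
    ``seed``. Hospitals never sampled get NaN bounds and n_draws = 0.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    y = np.asarray(y, dtype=float)
    hospital_ids = np.asarray(hospital_ids)
    hosp = np.unique(hospital_ids)
    rows_of = {h: np.flatnonzero(hospital_ids == h) for h in hosp}
    rng = np.random.default_rng(seed)
    draws: dict = {h: [] for h in hosp}
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    for _ in range(n_boot):
        sampled = rng.choice(hosp, size=len(hosp), replace=True)
        idx_parts, ids_parts = [], []
        for k, h in enumerate(sampled):
            ridx = rows_of[h]
            idx_parts.append(ridx)
            ids_parts.append(np.full(len(ridx), k))  # copies kept distinct
        rows = np.concatenate(idx_parts)
        ids = np.concatenate(ids_parts)
        Xb = Xv[rows]
        yb = y[rows]
        try:
            Xb_df = pd.DataFrame(Xb, columns=cols) if cols else Xb
            fit = fit_hierarchical(Xb_df, yb, ids, spec)
            prof = rsp(fit, Xb_df, ids, float(np.mean(yb)))
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            continue  # replicate discarded; rare degenerate resample
        vals = prof["rsp"].to_numpy()
        for k, h in enumerate(sampled):
            draws[h].append(vals[k])
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    out = []
    for h in hosp:
        d = draws[h]
        if d:
            lo, hi = np.percentile(d, [100 * lo_q, 100 * hi_q])
        else:
            lo = hi = np.nan
        out.append({"hospital_id": h, "ci_lower": lo, "ci_upper": hi,
                    "n_draws": len(d)})
    return pd.DataFrame(out).set_index("hospital_id")


def categorize(
    profiles: pd.DataFrame,
    national_mean: float,
    min_cases: int = 25,
) -> pd.DataFrame:
    """Assign the 3-way performance category to eligible hospitals.

    Eligible means n_cases >= min_cases and a defined CI. ci_lower above
    the national mean -> "higher"; ci_upper below it -> "lower"; otherwise
    "no_different". Ineligible hospitals keep a missing category.
    """
    out = profiles.copy()
    out["eligible"] = (out["n_cases"] >= min_cases) & out["ci_lower"].notna()
    cat = pd.Series(pd.NA, index=out.index, dtype="object")
    el = out["eligible"]
    cat[el & (out["ci_lower"] > national_mean)] = "higher"
    cat[el & (out["ci_upper"] < national_mean)] = "lower"
    cat[el & cat.isna()] = "no_different"
    out["category"] = cat
    return out


@dataclass
class CategoryShiftTable:
    """3x3 cross-classification of hospitals by category under two models."""

    counts: pd.DataFrame  # rows = model A, columns = model B
    pct_reclassified: float

    @property
    def n_hospitals(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def model_a_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def model_b_counts(self) -> pd.Series:
        return self.counts.sum(axis=0)


def shift_table_from_counts(counts: pd.DataFrame) -> CategoryShiftTable:
    """Build the shift summary from an explicit 3x3 count table."""
    counts = counts.reindex(index=CATEGORIES, columns=CATEGORIES).fillna(0)
    counts = counts.astype(int)
    total = counts.to_numpy().sum()
    if total == 0:
        raise ValueError("empty shift table")
    off = total - np.trace(counts.to_numpy())
    return CategoryShiftTable(
        counts=counts, pct_reclassified=100.0 * off / total
    )


def shift_table(categories_a: pd.Series, categories_b: pd.Series) -> CategoryShiftTable:
    """Cross-classify hospitals categorized under both models."""
    a = categories_a.dropna()
    b = categories_b.dropna()
    common = a.index.intersection(b.index)
    if not (len(common) == len(a) == len(b)):
        raise ValueError("hospital sets differ between the two models")
    tab = pd.crosstab(a[common], b[common])
    return shift_table_from_counts(tab)


def infer_extreme_shifts(
    lower_a: int,
    lower_b: int,
    lower_to_no: int,
    no_to_lower: int,
    extreme_total: int,
) -> tuple[int, int]:
    """Split the lower<->higher shifts by the category-count identity.

    model-B lower = lower_a - lower_to_no - (lower->higher)
                    + no_to_lower + (higher->lower),
    with (lower->higher) + (higher->lower) = extreme_total. Returns
    (lower_to_higher, higher_to_lower).
    """
    diff = lower_b - (lower_a - lower_to_no + no_to_lower)  # = hl - lh
    if (extreme_total + diff) % 2 != 0:
        raise ValueError("counts are inconsistent with an integer split")
    hl = (extreme_total + diff) // 2
    lh = extreme_total - hl
    if hl < 0 or lh < 0:
        raise ValueError("counts admit no non-negative split")
    return lh, hl


def profile_hospitals(
    X: pd.DataFrame,
    y,
    hospital_ids,
    spec: GLMSpec,
    n_boot: int = 2000,
    seed: int = 0,
    min_cases: int = 25,
) -> pd.DataFrame:
    """End-to-end profiling: hierarchical fit, RSP, bootstrap CI, category.

    The national mean is the observed mean (winsorized) payment over all
    admissions, including those at hospitals below the case threshold.
    """
    y = np.asarray(y, dtype=float)
    national_mean = float(np.mean(y))
    fit = fit_hierarchical(X, y, hospital_ids, spec)
    prof = rsp(fit, X, hospital_ids, national_mean)
    ci = bootstrap_ci(X, y, hospital_ids, spec, n_boot=n_boot, seed=seed)
    prof = prof.join(ci)
    prof = categorize(prof, national_mean, min_cases=min_cases)
    prof.attrs["national_mean"] = national_mean
    prof.attrs["tau"] = fit.tau
    prof.attrs["bootstrap"] = {
        "unit": "hospital-cluster", "type": "percentile",
        "n_boot": n_boot, "seed": seed,
    }
    return prof
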