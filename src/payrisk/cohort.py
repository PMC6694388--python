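"""Condition-cohort construction: inclusion rules and the winsorized
30-day payment outcome.

Inclusion follows the published payment measures: age 65+ at the index
admission, a full 12 months of prior fee-for-service enrollment, decedents
retained with unprorated payments. The standardized payment is winsorized
at the 99.5th percentile of the analytic cohort to limit outlier influence.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import ClaimsBundle

log = logging.getLogger(__name__)

AGE_BANDS = ("<=74", "75-84", ">=85")

COHORT_COLUMNS = [
    "admission_id", "patient_id", "hospital_id", "condition",
    "age_band", "payment_w", "died_30d",
]


def winsorize(payments, upper_q: float = 0.995) -> np.ndarray:
    """Cap values above the empirical ``upper_q`` quantile at that quantile.

    One-sided (upper only); the quantile uses linear interpolation between
    order statistics, so the cap itself may fall between observed values.
    Re-winsorizing is monotone non-increasing and touches only values at
    the cap; it is exactly idempotent whenever the quantile lands on an
    order statistic (in particular at upper_q = 1.0 or with ties at the
    cap), but the interpolated cap of already-capped data can sit slightly
    below the original cap.
    """
    x = np.asarray(payments, dtype=float)
    if x.size == 0:
        raise ValueError("payments must be nonempty")
    if not (x > 0).all():
        raise ValueError("payments must be strictly positive")
    if not 0.0 < upper_q <= 1.0:
        raise ValueError(f"upper_q must lie in (0, 1], got {upper_q}")
    cap = np.quantile(x, upper_q)  # linear interpolation (default)
    return np.minimum(x, cap)


def assign_age_band(age_years) -> pd.Series:
    """Categorical age at the index admission: <=74, 75-84, >=85."""
    age = pd.Series(age_years)
    band = pd.Series(np.select(
        [age <= 74, age <= 84], [AGE_BANDS[0], AGE_BANDS[1]], AGE_BANDS[2]
    ), index=age.index)
    return band


def build_cohort(
    bundle: ClaimsBundle,
    condition: str,
    winsor_q: float = 0.995,
) -> pd.DataFrame:
    """Apply the inclusion rules for one condition and winsorize payments.

    Keeps admissions with the matching cohort condition, age >= 65 and
    prior_ffs_months >= 12; 30-day decedents stay in. The winsorization cap
    is computed on this cohort's payments, after the filters.
    """
    adm = bundle.index_admissions.merge(
        bundle.enrollment, on="patient_id", how="left", validate="m:1"
    )
    keep = (
        (adm["condition"] == condition)
        & (adm["age_years"] >= 65)
        & (adm["prior_ffs_months"].fillna(0) >= 12)
    )
    rows = adm.loc[keep].copy()
    if rows.empty:
        log.warning("cohort for condition %r is empty", condition)
        return pd.DataFrame(columns=COHORT_COLUMNS)
    rows["age_band"] = assign_age_band(rows["age_years"]).values
    rows["payment_w"] = winsorize(rows["payment_30d"].values, winsor_q)
    out = rows[COHORT_COLUMNS].reset_index(drop=True)
    out.attrs["condition"] = condition
    out.attrs["winsor_q"] = winsor_q
    out.attrs["winsor_cap"] = float(np.quantile(rows["payment_30d"], winsor_q))
    return out
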