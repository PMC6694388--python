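"""Synthetic Medicare-style claims generator.

Emulates the statistical structure the payment models assume: a mostly-65+
population admitted for one of three cohort conditions (AMI, HF, PN),
hospitals whose case volumes straddle the 25-case profiling threshold,
diagnosis codes arriving through three channels (index principal, index
secondary, 12-month history) with POA flags on index rows, 30-day
standardized payments drawn from the condition's GLM family/link around a
linear predictor with a hospital random intercept, and a configurable
fraction of patients lacking 12 months of continuous fee-for-service
enrollment. Ground truth (coefficients, hospital effects, dispersion) is
recorded so estimators can be tested by parameter recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("AMI", "HF", "PN")
CHANNELS = ("index", "history")
POA_TOKENS = ("Y", "N", "missing")

#: family/link pairs used by the published payment measures
DEFAULT_FAMILY_LINK: dict[str, tuple[str, str]] = {
    "AMI": ("inverse_gaussian", "log"),
    "HF": ("gamma", "log"),
    "PN": ("gamma", "identity"),
}

ADMISSION_COLUMNS = [
    "admission_id", "patient_id", "hospital_id", "condition",
    "age_years", "payment_30d", "died_30d",
]
DIAGNOSIS_COLUMNS = ["admission_id", "code", "role", "poa", "window"]
ENROLLMENT_COLUMNS = ["patient_id", "prior_ffs_months"]


@dataclass(frozen=True)
class CodeSpec:
    """Per-code arrival rates for the three diagnosis channels plus the POA
    flag distribution of its index-secondary rows."""

    code: str
    p_principal: float = 0.0   # sampling weight for the single principal dx
    p_secondary: float = 0.0   # per-admission Bernoulli, index secondary
    p_history: float = 0.0     # per-admission Bernoulli, 12-month history
    poa_probs: tuple[float, float, float] = (0.80, 0.12, 0.08)  # Y, N, missing

    def __post_init__(self) -> None:
        for p in (self.p_principal, self.p_secondary, self.p_history):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.code}: probabilities must be in [0,1]")
        if abs(sum(self.poa_probs) - 1.0) > 1e-9 or min(self.poa_probs) < 0:
            raise ValueError(f"{self.code}: poa_probs must be a distribution")


@dataclass(frozen=True)
class ConditionTruth:
    """True payment model for one condition, on the link scale.

    ``code_effects`` is keyed by ``(code, channel)`` with channel in
    {"index", "history"}; an index effect fires when the code appears as the
    principal or any secondary diagnosis of the index stay (POA flags are an
    observation layer and do not alter the physical comorbidity).
    """

    intercept: float
    age_75_84: float = 0.0
    age_85p: float = 0.0
    code_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimTruth:
    """Generator ground truth recorded alongside a bundle."""

    true_beta: Mapping[str, ConditionTruth]
    hospital_effects: pd.Series  # link-scale, indexed by hospital_id
    dispersion: Mapping[str, float]
    re_sd: float

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimTruth):
            return NotImplemented
        return (
            self.true_beta == other.true_beta
            and self.dispersion == dict(other.dispersion)
            and self.re_sd == other.re_sd
            and self.hospital_effects.equals(other.hospital_effects)
        )


def make_catalog(
    n_codes: int = 60,
    poa_all_yes: bool = False,
    start: int = 1,
) -> list[CodeSpec]:
    """Deterministic code catalog whose secondary/history prevalences cycle
    through a spread straddling the 0.5% candidate-frequency filter."""
    sec_cycle = [0.002, 0.004, 0.008, 0.015, 0.03, 0.06, 0.12, 0.20]
    his_cycle = [0.25, 0.10, 0.05, 0.02, 0.012, 0.006, 0.004, 0.003]
    poa_cycle = [
        (0.85, 0.10, 0.05),
        (0.70, 0.25, 0.05),
        (0.60, 0.10, 0.30),
        (0.90, 0.05, 0.05),
    ]
    out = []
    for i in range(n_codes):
        code = f"D{start + i:03d}"
        poa = (1.0, 0.0, 0.0) if poa_all_yes else poa_cycle[i % len(poa_cycle)]
        out.append(
            CodeSpec(
                code=code,
                # principal codes spread across the catalog so no single
                # category hierarchy group covers every admission
                p_principal=1.0 if i % 5 == 0 else 0.0,
                p_secondary=sec_cycle[i % len(sec_cycle)],
                p_history=his_cycle[i % len(his_cycle)],
                poa_probs=poa,
            )
        )
    return out


def _default_true_beta() -> dict[str, ConditionTruth]:
    # Intercepts put mean payments near the observed national means
    # (~$23k AMI, ~$16k HF, ~$17k PN); a handful of moderately common codes
    # carry index and/or history effects so every covariate scheme has
    # signal to find. Identity-link (PN) effects are in dollars.
    return {
        "AMI": ConditionTruth(
            intercept=math.log(21_000.0),
            age_75_84=0.06,
            age_85p=0.12,
            code_effects={
                ("D005", "index"): 0.35,
                ("D007", "index"): 0.22,
                ("D013", "index"): 0.18,
                ("D001", "history"): 0.15,
                ("D009", "history"): 0.12,
            },
        ),
        "HF": ConditionTruth(
            intercept=math.log(14_500.0),
            age_75_84=0.05,
            age_85p=0.10,
            code_effects={
                ("D006", "index"): 0.30,
                ("D014", "index"): 0.20,
                ("D021", "index"): 0.15,
                ("D002", "history"): 0.18,
                ("D017", "history"): 0.10,
            },
        ),
        "PN": ConditionTruth(
            intercept=15_000.0,
            age_75_84=900.0,
            age_85p=1_800.0,
            code_effects={
                ("D005", "index"): 4_500.0,
                ("D015", "index"): 3_000.0,
                ("D023", "index"): 2_000.0,
                ("D003", "history"): 2_500.0,
                ("D011", "history"): 1_500.0,
            },
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the generator.

    Defaults are a desk-scale analogue of the fee-for-service study
    population: ~65+ patients, three condition cohorts, ~20% of hospitals
    below the 25-case threshold, payment dispersions matching the observed
    coefficient of variation of 30-day payments, and 5% of patients without
    a full 12 months of prior enrollment.
    """

    n_patients: int = 20_000
    n_hospitals: int = 100
    hospital_volume_dist: Mapping[str, object] = field(
        default_factory=lambda: {
            "small_frac": 0.20, "small_range": (5, 24),
            "large_logmean": 5.0, "large_logsd": 0.5,
        }
    )
    condition_mix: Mapping[str, float] = field(
        default_factory=lambda: {"AMI": 0.18, "HF": 0.35, "PN": 0.47}
    )
    code_catalog: Sequence[CodeSpec] = field(default_factory=make_catalog)
    poa_exempt_codes: frozenset[str] = frozenset(
        ["D002", "D010", "D022", "D030", "D045"]
    )
    true_beta: Mapping[str, ConditionTruth] = field(
        default_factory=_default_true_beta
    )
    family_link: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_LINK)
    )
    dispersion: Mapping[str, float] = field(
        default_factory=lambda: {"AMI": 2.7e-5, "HF": 0.55, "PN": 0.45}
    )
    re_sd: float = 0.0
    frac_short_enrollment: float = 0.05
    frac_under_65: float = 0.02
    death_prob: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_hospitals < 1:
            raise ValueError("n_patients and n_hospitals must be positive")
        mix = dict(self.condition_mix)
        if abs(sum(mix.values()) - 1.0) > 1e-9 or min(mix.values()) < 0:
            raise ValueError("condition_mix must be a distribution")
        unknown = set(mix) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions in mix: {sorted(unknown)}")
        for c, phi in self.dispersion.items():
            if phi <= 0:
                raise ValueError(f"dispersion for {c} must be > 0")
        if self.re_sd < 0:
            raise ValueError("re_sd must be >= 0")
        for frac in (self.frac_short_enrollment, self.frac_under_65):
            if not 0.0 <= frac < 1.0:
                raise ValueError("fractions must lie in [0, 1)")
        for c, (fam, link) in self.family_link.items():
            if fam not in ("gamma", "inverse_gaussian"):
                raise ValueError(f"unknown family {fam!r} for {c}")
            if link not in ("log", "identity"):
                raise ValueError(f"unknown link {link!r} for {c}")


@dataclass
class ClaimsBundle:
    """Linked index-admission, diagnosis and enrollment tables, plus the
    generator's ground truth when synthetic."""

    index_admissions: pd.DataFrame
    diagnoses: pd.DataFrame
    enrollment: pd.DataFrame
    truth: SimTruth | None = None

    def validate(self) -> "ClaimsBundle":
        _check_columns(self.index_admissions, ADMISSION_COLUMNS,
                       "index_admissions")
        _check_columns(self.diagnoses, DIAGNOSIS_COLUMNS, "diagnoses")
        _check_columns(self.enrollment, ENROLLMENT_COLUMNS, "enrollment")
        adm = set(self.index_admissions["admission_id"])
        orphans = set(self.diagnoses["admission_id"]) - adm
        if orphans:
            raise ValueError(
                f"diagnoses reference unknown admissions: "
                f"{sorted(orphans)[:5]} (n={len(orphans)})"
            )
        if len(self.index_admissions):
            if not (self.index_admissions["payment_30d"] > 0).all():
                raise ValueError("payment_30d must be strictly positive")
        idx = self.diagnoses["window"] == "index"
        bad = self.diagnoses.loc[idx, "poa"].isna()
        if bad.any():
            raise ValueError("index diagnosis rows must carry a POA flag")
        tok = ~self.diagnoses.loc[idx, "poa"].isin(POA_TOKENS)
        if tok.any():
            raise ValueError(
                "unknown POA tokens: "
                f"{sorted(self.diagnoses.loc[idx].loc[tok, 'poa'].unique())}"
            )
        if self.diagnoses.loc[~idx, "poa"].notna().any():
            raise ValueError("history rows must not carry a POA flag")
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClaimsBundle):
            return NotImplemented
        return (
            self.index_admissions.reset_index(drop=True).equals(
                other.index_admissions.reset_index(drop=True))
            and self.diagnoses.reset_index(drop=True).equals(
                other.diagnoses.reset_index(drop=True))
            and self.enrollment.reset_index(drop=True).equals(
                other.enrollment.reset_index(drop=True))
            and self.truth == other.truth
        )


def _check_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table is missing columns {missing}")


def _inv_link(eta: np.ndarray, link: str) -> np.ndarray:
    return np.exp(eta) if link == "log" else eta


def generate_bundle(config: SimConfig) -> ClaimsBundle:
    """Draw a full claims bundle; deterministic given ``config.seed``.

    Payments follow the configured family with mean g^-1(x'beta + alpha_h)
    and variance phi*mu^2 (Gamma) or phi*mu^3 (inverse Gaussian), matching
    the GLM variance functions the estimators assume. Identity-link
    configurations whose realized linear predictor is non-positive are
    rejected with a diagnostic rather than silently truncated.
    """
    ss = np.random.SeedSequence(config.seed)
    names = ("patients", "hospitals", "principal", "secondary",
             "history", "poa", "payment", "death")
    rngs = {k: np.random.default_rng(s) for k, s in zip(names, ss.spawn(len(names)))}

    n = config.n_patients
    rp = rngs["patients"]

    # --- ages: small under-65 tail, then three bands roughly matching the
    # observed cohort age distribution (30% / 37% / 33%)
    age = np.empty(n, dtype=np.int64)
    under = rp.random(n) < config.frac_under_65
    age[under] = rp.integers(60, 65, under.sum())
    band = rp.choice(3, size=n, p=[0.30, 0.37, 0.33])
    lo = np.array([65, 75, 85]); hi = np.array([75, 85, 100])
    over = ~under
    age[over] = rp.integers(lo[band[over]], hi[band[over]])

    conds = list(config.condition_mix)
    condition = rp.choice(conds, size=n, p=[config.condition_mix[c] for c in conds])

    # --- enrollment: exact count of short-enrollment patients by construction
    n_short = int(round(config.frac_short_enrollment * n))
    short_ids = rp.choice(n, size=n_short, replace=False)
    months = rp.integers(12, 121, n)
    months[short_ids] = rp.integers(0, 12, n_short)

    # --- hospitals: volumes straddle the 25-case threshold
    rh = rngs["hospitals"]
    H = config.n_hospitals
    vd = dict(config.hospital_volume_dist)
    if "fixed" in vd:
        weights = np.full(H, float(vd["fixed"]))
    else:
        small = rh.random(H) < float(vd.get("small_frac", 0.2))
        s_lo, s_hi = vd.get("small_range", (5, 24))
        weights = rh.lognormal(float(vd.get("large_logmean", 5.0)),
                               float(vd.get("large_logsd", 0.5)), H)
        weights[small] = rh.integers(int(s_lo), int(s_hi) + 1, small.sum())
    hospital = rh.choice(H, size=n, p=weights / weights.sum())
    alpha = rh.normal(0.0, config.re_sd, H) if config.re_sd > 0 else np.zeros(H)

    admission_id = np.arange(1, n + 1)
    patient_id = np.arange(100_001, 100_001 + n)

    # --- diagnoses
    cat = list(config.code_catalog)
    codes = np.array([c.code for c in cat])
    pw = np.array([c.p_principal for c in cat], dtype=float)
    if pw.sum() <= 0:
        raise ValueError("code_catalog must give positive principal weight")
    principal_idx = rngs["principal"].choice(len(cat), size=n, p=pw / pw.sum())

    p_sec = np.array([c.p_secondary for c in cat])
    p_his = np.array([c.p_history for c in cat])
    sec = rngs["secondary"].random((n, len(cat))) < p_sec
    his = rngs["history"].random((n, len(cat))) < p_his
    # the principal code is not duplicated as a secondary row
    sec[np.arange(n), principal_idx] = False

    rows_adm: list[np.ndarray] = []
    rows_code: list[np.ndarray] = []
    rows_role: list[np.ndarray] = []
    rows_poa: list[np.ndarray] = []
    rows_win: list[np.ndarray] = []

    rows_adm.append(admission_id)
    rows_code.append(codes[principal_idx])
    rows_role.append(np.full(n, "principal"))
    rows_poa.append(np.full(n, "Y", dtype=object))
    rows_win.append(np.full(n, "index"))

    rpoa = rngs["poa"]
    a_sec, c_sec = np.nonzero(sec)
    poa_sec = np.empty(len(c_sec), dtype=object)
    for j, spec_j in enumerate(cat):
        m = c_sec == j
        if m.any():
            poa_sec[m] = rpoa.choice(POA_TOKENS, size=m.sum(), p=spec_j.poa_probs)
    rows_adm.append(admission_id[a_sec])
    rows_code.append(codes[c_sec])
    rows_role.append(np.full(len(a_sec), "secondary"))
    rows_poa.append(poa_sec)
    rows_win.append(np.full(len(a_sec), "index"))

    a_his, c_his = np.nonzero(his)
    rows_adm.append(admission_id[a_his])
    rows_code.append(codes[c_his])
    rows_role.append(np.full(len(a_his), "secondary"))
    rows_poa.append(np.full(len(a_his), None, dtype=object))
    rows_win.append(np.full(len(a_his), "history"))

    diagnoses = pd.DataFrame({
        "admission_id": np.concatenate(rows_adm),
        "code": np.concatenate(rows_code),
        "role": np.concatenate(rows_role),
        "poa": np.concatenate(rows_poa),
        "window": np.concatenate(rows_win),
    }).sort_values(["admission_id", "window", "role", "code"],
                   kind="stable").reset_index(drop=True)

    # --- payments from the true model
    code_pos = {c.code: j for j, c in enumerate(cat)}
    index_presence = sec.copy()
    index_presence[np.arange(n), principal_idx] = True
    eta = np.zeros(n)
    payment = np.empty(n)
    rpay = rngs["payment"]
    for c in conds:
        m = condition == c
        if not m.any():
            continue
        tb = config.true_beta[c]
        e = np.full(m.sum(), tb.intercept, dtype=float)
        ages = age[m]
        e += np.where((ages >= 75) & (ages <= 84), tb.age_75_84, 0.0)
        e += np.where(ages >= 85, tb.age_85p, 0.0)
        for (code, channel), b in tb.code_effects.items():
            j = code_pos.get(code)
            if j is None:
                raise ValueError(f"true effect on unknown code {code!r}")
            pres = index_presence[m, j] if channel == "index" else his[m, j]
            e += b * pres
        e += alpha[hospital[m]]
        fam, link = config.family_link[c]
        mu = _inv_link(e, link)
        if (mu <= 0).any():
            raise ValueError(
                f"condition {c}: identity-link linear predictor is "
                f"non-positive for {(mu <= 0).sum()} admissions; "
                "adjust intercept/effects"
            )
        phi = config.dispersion[c]
        if fam == "gamma":
            payment[m] = rpay.gamma(shape=1.0 / phi, scale=phi * mu)
        else:  # inverse Gaussian, Var = phi * mu^3
            payment[m] = rpay.wald(mu, 1.0 / phi)
        eta[m] = e

    died = (rngs["death"].random(n) < config.death_prob).astype(np.int64)

    index_admissions = pd.DataFrame({
        "admission_id": admission_id,
        "patient_id": patient_id,
        "hospital_id": hospital + 1,
        "condition": condition,
        "age_years": age,
        "payment_30d": payment,
        "died_30d": died,
    })
    enrollment = pd.DataFrame({
        "patient_id": patient_id,
        "prior_ffs_months": months,
    })
    truth = SimTruth(
        true_beta=dict(config.true_beta),
        hospital_effects=pd.Series(alpha, index=pd.RangeIndex(1, H + 1),
                                   name="alpha"),
        dispersion=dict(config.dispersion),
        re_sd=config.re_sd,
    )
    return ClaimsBundle(index_admissions, diagnoses, enrollment, truth).validate()


# ---------------------------------------------------------------------------
# plain-text round-trip

def write_bundle(bundle: ClaimsBundle, path: str | Path) -> Path:
    """Write the three CSV tables (and a JSON truth sidecar if present)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.index_admissions.to_csv(path / "index_admissions.csv", index=False)
    bundle.diagnoses.to_csv(path / "diagnoses.csv", index=False)
    bundle.enrollment.to_csv(path / "enrollment.csv", index=False)
    if bundle.truth is not None:
        t = bundle.truth
        doc = {
            "true_beta": {
                c: {
                    "intercept": tb.intercept,
                    "age_75_84": tb.age_75_84,
                    "age_85p": tb.age_85p,
                    "code_effects": [
                        {"code": k[0], "channel": k[1], "beta": v}
                        for k, v in tb.code_effects.items()
                    ],
                }
                for c, tb in t.true_beta.items()
            },
            "hospital_effects": {
                str(k): v for k, v in t.hospital_effects.items()
            },
            "dispersion": dict(t.dispersion),
            "re_sd": t.re_sd,
        }
        (path / "truth.json").write_text(json.dumps(doc, indent=1))
    return path


def read_bundle(path: str | Path) -> ClaimsBundle:
    """Read a bundle written by :func:`write_bundle`; validates schema."""
    path = Path(path)
    for name in ("index_admissions.csv", "diagnoses.csv", "enrollment.csv"):
        if not (path / name).exists():
            raise FileNotFoundError(f"{path / name} not found")
    adm = pd.read_csv(path / "index_admissions.csv",
                      float_precision="round_trip")
    dx = pd.read_csv(path / "diagnoses.csv",
                     dtype={"poa": object}, keep_default_na=True)
    if "poa" in dx.columns:
        dx["poa"] = dx["poa"].where(dx["poa"].notna(), None)
    enr = pd.read_csv(path / "enrollment.csv", float_precision="round_trip")
    truth = None
    tp = path / "truth.json"
    if tp.exists():
        doc = json.loads(tp.read_text())
        true_beta = {
            c: ConditionTruth(
                intercept=d["intercept"],
                age_75_84=d["age_75_84"],
                age_85p=d["age_85p"],
                code_effects={
                    (e["code"], e["channel"]): e["beta"]
                    for e in d["code_effects"]
                },
            )
            for c, d in doc["true_beta"].items()
        }
        he = pd.Series(
            {int(k): v for k, v in doc["hospital_effects"].items()},
            name="alpha",
        )
        he.index = pd.RangeIndex(he.index.min(), he.index.max() + 1)
        truth = SimTruth(true_beta=true_beta, hospital_effects=he,
                         dispersion=doc["dispersion"], re_sd=doc["re_sd"])
    return ClaimsBundle(adm, dx, enr, truth).validate()
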