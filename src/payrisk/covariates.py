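"""Candidate-variable construction: the seven covariate schemes.

Comorbidity information arrives through two channels — the index admission
claim and all claims in the 12 months before it — and can enter a model
either grouped into condition categories (CCs, with a severity hierarchy)
or as individual diagnosis codes filtered by frequency. The scheme ladder:

==================  ========================================================
cms_base            CC indicators, channels pooled, index-only potential
                    complications removed by the exclusion algorithm
cms_poa             same grouping, but the POA rule replaces the exclusion
                    algorithm
hcc_index           CC indicators from the index admission only
hcc_pooled          one indicator per CC: present in index OR history
hcc_separate        distinct indicators per (CC, channel)
codes_index         individual codes from the index admission, frequency
                    filtered
codes_index_history individual codes per channel, frequency filtered per
                    channel
==================  ========================================================

Every design matrix carries two forced age-band indicators (reference
<=74). All schemes except cms_base apply the POA eligibility rule to index
secondary diagnoses first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .codemaps import CodeMaps
from .simulate import ClaimsBundle, POA_TOKENS

SCHEME_NAMES = (
    "cms_base", "cms_poa", "hcc_index", "hcc_pooled", "hcc_separate",
    "codes_index", "codes_index_history",
)

AGE_COLUMNS = ("age_75_84", "age_85p")


@dataclass(frozen=True)
class Scheme:
    """A named covariate scheme plus its parameters."""

    name: str
    maps: CodeMaps
    freq_threshold: float = 0.005

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(
                f"unknown scheme {self.name!r}; expected one of {SCHEME_NAMES}"
            )
        if not 0.0 <= self.freq_threshold < 1.0:
            raise ValueError("freq_threshold must lie in [0, 1)")

    @property
    def unit(self) -> str:
        return "code" if self.name.startswith("codes") else "cc"


@dataclass
class DesignMatrix:
    """Binary risk indicators plus forced age columns, one row per
    admission. ``provenance`` records each column's channel and unit."""

    X: pd.DataFrame
    provenance: Mapping[str, dict]
    forced: tuple[str, ...] = AGE_COLUMNS
    unmapped_codes: int = 0

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


def poa_eligible(dx_rows: pd.DataFrame, maps: CodeMaps) -> pd.DataFrame:
    """Filter index-window diagnoses by the present-on-admission rule.

    Principal diagnoses are always eligible. A secondary diagnosis is kept
    iff its POA flag is "Y", or the flag is "missing" and the code is on
    the POA-exempt list; "N" rows are dropped. Idempotent.
    """
    if dx_rows.empty:
        return dx_rows
    poa = dx_rows["poa"]
    bad = ~poa.isin(POA_TOKENS) & poa.notna()
    if bad.any() or poa.isna().any():
        tokens = sorted(set(poa[bad].astype(str))) if bad.any() else ["<NA>"]
        raise ValueError(f"unknown POA tokens in index rows: {tokens}")
    keep = (
        (dx_rows["role"] == "principal")
        | (poa == "Y")
        | ((poa == "missing") & dx_rows["code"].isin(maps.poa_exempt))
    )
    return dx_rows.loc[keep]


def map_to_ccs(
    codes: Iterable[str],
    maps: CodeMaps,
    counter: dict | None = None,
) -> set[str]:
    """Map codes to condition categories and apply hierarchy suppression.

    Unmapped codes are ignored; if ``counter`` is given its "unmapped" key
    is incremented per ignored code.
    """
    ccs: set[str] = set()
    unmapped = 0
    for c in codes:
        cc = maps.code_to_cc.get(c)
        if cc is None:
            unmapped += 1
        else:
            ccs.add(cc)
    if counter is not None:
        counter["unmapped"] = counter.get("unmapped", 0) + unmapped
    for group in maps.hierarchies:
        for rank, cc in enumerate(group):
            if cc in ccs:
                ccs.difference_update(group[rank + 1:])
                break
    return ccs


def base_model_exclusion(
    index_dx: pd.DataFrame,
    history_dx: pd.DataFrame,
    maps: CodeMaps,
) -> pd.DataFrame:
    """Drop index secondary diagnoses that may be complications of care.

    An index secondary diagnosis whose category is on the excludable list
    is removed unless the same category also arises from that admission's
    12-month history — the pre-POA proxy for "present on admission".
    Principal diagnoses are always kept.
    """
    if index_dx.empty:
        return index_dx
    cc_of = lambda s: s.map(maps.code_to_cc)  # noqa: E731
    idx_cc = cc_of(index_dx["code"])
    excludable = idx_cc.isin(maps.complication_excludable_ccs)
    # per-admission set of history categories (pre-hierarchy: the question
    # is whether the same category was coded before, not which survives)
    his_pairs = set()
    if not history_dx.empty:
        hcc = cc_of(history_dx["code"])
        m = hcc.notna()
        his_pairs = set(zip(history_dx.loc[m, "admission_id"], hcc[m]))
    in_history = pd.Series(
        [(a, c) in his_pairs for a, c in zip(index_dx["admission_id"], idx_cc)],
        index=index_dx.index,
    )
    keep = (
        (index_dx["role"] == "principal")
        | ~excludable
        | in_history
    )
    return index_dx.loc[keep]


def frequency_filter(
    dx_rows: pd.DataFrame,
    n_cohort: int,
    threshold: float = 0.005,
) -> list[str]:
    """Codes carried by strictly more than ``threshold`` of admissions.

    A code appearing several times in one admission counts once; the
    denominator is the cohort size, not the number of admissions with any
    diagnosis.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    if n_cohort <= 0:
        raise ValueError("cohort is empty")
    if dx_rows.empty:
        return []
    counts = (
        dx_rows.drop_duplicates(["admission_id", "code"])
        .groupby("code", sort=True)
        .size()
    )
    return list(counts.index[counts / n_cohort > threshold])


def _indicator_frame(
    pairs: pd.DataFrame,  # columns: admission_id, col
    admission_ids: pd.Index,
    columns: list[str],
) -> pd.DataFrame:
    X = pd.DataFrame(
        np.zeros((len(admission_ids), len(columns)), dtype=np.int8),
        index=admission_ids, columns=columns,
    )
    if len(pairs):
        sub = pairs[pairs["col"].isin(columns)]
        rows = X.index.get_indexer(sub["admission_id"])
        cols = X.columns.get_indexer(sub["col"])
        X.values[rows, cols] = 1
    return X


def _cc_pairs(dx: pd.DataFrame, maps: CodeMaps, counter: dict) -> pd.DataFrame:
    """Per-admission hierarchy-resolved category memberships."""
    out_a, out_c = [], []
    for adm, grp in dx.groupby("admission_id", sort=True):
        for cc in sorted(map_to_ccs(grp["code"], maps, counter)):
            out_a.append(adm)
            out_c.append(cc)
    return pd.DataFrame({"admission_id": out_a, "col": out_c})


def build_design(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    scheme: Scheme,
) -> DesignMatrix:
    """Build the binary design matrix for one cohort under one scheme.

    Invariant to the row order of the diagnosis table; every cohort
    admission appears as a row even with no diagnoses (age columns only).
    """
    maps = scheme.maps
    adm_ids = pd.Index(cohort["admission_id"], name="admission_id")
    dx = bundle.diagnoses[bundle.diagnoses["admission_id"].isin(adm_ids)]
    index_dx = dx[dx["window"] == "index"]
    history_dx = dx[dx["window"] == "history"]

    if scheme.name == "cms_base":
        index_dx = base_model_exclusion(index_dx, history_dx, maps)
    else:
        index_dx = poa_eligible(index_dx, maps)

    counter: dict = {}
    provenance: dict[str, dict] = {}
    n = len(adm_ids)

    if scheme.name in ("cms_base", "cms_poa"):
        # channels pooled before grouping: hierarchy acts on the union
        pooled = pd.concat([index_dx, history_dx], ignore_index=True)
        pairs = _cc_pairs(pooled, maps, counter)
        cols = sorted(pairs["col"].unique()) if len(pairs) else []
        X = _indicator_frame(pairs, adm_ids, cols)
        provenance.update({c: {"channel": "pooled", "unit": "cc"} for c in cols})
    elif scheme.name == "hcc_index":
        pairs = _cc_pairs(index_dx, maps, counter)
        cols = sorted(pairs["col"].unique()) if len(pairs) else []
        X = _indicator_frame(pairs, adm_ids, cols)
        provenance.update({c: {"channel": "index", "unit": "cc"} for c in cols})
    elif scheme.name in ("hcc_pooled", "hcc_separate"):
        # hierarchy resolved within each channel; the pooled indicator is
        # then the OR of the two channel indicators (a risk factor is "yes"
        # if the patient had a history or index diagnosis or both)
        pi = _cc_pairs(index_dx, maps, counter)
        ph = _cc_pairs(history_dx, maps, counter)
        if scheme.name == "hcc_pooled":
            pairs = pd.concat([pi, ph], ignore_index=True).drop_duplicates()
            cols = sorted(pairs["col"].unique()) if len(pairs) else []
            X = _indicator_frame(pairs, adm_ids, cols)
            provenance.update(
                {c: {"channel": "pooled", "unit": "cc"} for c in cols})
        else:
            pi = pi.assign(col=pi["col"] + "__index")
            ph = ph.assign(col=ph["col"] + "__history")
            pairs = pd.concat([pi, ph], ignore_index=True)
            cols = sorted(pairs["col"].unique()) if len(pairs) else []
            X = _indicator_frame(pairs, adm_ids, cols)
            for c in cols:
                channel = "index" if c.endswith("__index") else "history"
                provenance[c] = {"channel": channel, "unit": "cc"}
    elif scheme.name == "codes_index":
        cand = frequency_filter(index_dx, n, scheme.freq_threshold)
        pairs = (index_dx[index_dx["code"].isin(cand)]
                 .rename(columns={"code": "col"})[["admission_id", "col"]]
                 .drop_duplicates())
        X = _indicator_frame(pairs, adm_ids, sorted(cand))
        provenance.update(
            {c: {"channel": "index", "unit": "code"} for c in cand})
    elif scheme.name == "codes_index_history":
        ci = frequency_filter(index_dx, n, scheme.freq_threshold)
        ch = frequency_filter(history_dx, n, scheme.freq_threshold)
        pi = (index_dx[index_dx["code"].isin(ci)]
              .assign(col=lambda d: d["code"] + "__index"))
        ph = (history_dx[history_dx["code"].isin(ch)]
              .assign(col=lambda d: d["code"] + "__history"))
        pairs = pd.concat(
            [pi[["admission_id", "col"]], ph[["admission_id", "col"]]],
            ignore_index=True).drop_duplicates()
        cols = sorted([c + "__index" for c in ci] + [c + "__history" for c in ch])
        X = _indicator_frame(pairs, adm_ids, cols)
        for c in cols:
            channel = "index" if c.endswith("__index") else "history"
            provenance[c] = {"channel": channel, "unit": "code"}
    else:  # pragma: no cover - guarded by Scheme.__post_init__
        raise ValueError(f"unknown scheme {scheme.name!r}")

    band = cohort.set_index("admission_id")["age_band"].reindex(adm_ids)
    X["age_75_84"] = (band == "75-84").astype(np.int8).values
    X["age_85p"] = (band == ">=85").astype(np.int8).values
    provenance["age_75_84"] = {"channel": "demographic", "unit": "age"}
    provenance["age_85p"] = {"channel": "demographic", "unit": "age"}
    return DesignMatrix(
        X=X, provenance=provenance, forced=AGE_COLUMNS,
        unmapped_codes=counter.get("unmapped", 0),
    )


def write_design(design: DesignMatrix, path) -> None:
    """Sparse triplet file plus a column dictionary with provenance."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows, cols = np.nonzero(design.X.values)
    trip = pd.DataFrame({
        "admission_id": design.X.index[rows],
        "column": design.X.columns[cols],
        "value": 1,
    })
    trip.to_csv(path / "design_triplets.csv", index=False)
    pd.DataFrame([
        {"column": c, **design.provenance[c],
         "forced": c in design.forced}
        for c in design.X.columns
    ]).to_csv(path / "design_columns.csv", index=False)
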