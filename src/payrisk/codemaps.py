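"""Diagnosis-code lookup tables: code-to-category crosswalk, category
hierarchies, the POA-exempt code list, and the set of categories excludable
as potential complications of care.

The tables shipped under ``payrisk/data`` are small synthetic stand-ins with
the same file format as the real (licensed) CMS v22 tables; users supply
their own CSVs via :meth:`CodeMaps.from_dir` to run with production maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = ["CodeMaps", "load_toy_maps"]


@dataclass(frozen=True)
class CodeMaps:
    """Lookup tables driving comorbidity-variable construction.

    Parameters
    ----------
    code_to_cc
        Diagnosis code -> condition-category id. Codes absent from the map
        are simply not grouped (callers count them, they are not errors).
    hierarchies
        Ordered tuples of category ids, highest (most severe) rank first.
        Within a group, the best-ranked category present suppresses every
        lower-ranked one.
    poa_exempt
        Codes exempt from present-on-admission reporting; a missing POA flag
        on an exempt code is treated as present on admission.
    complication_excludable_ccs
        Categories that, when seen only during the index stay, may be
        complications of care and are excluded by the base-model algorithm.
    """

    code_to_cc: Mapping[str, str]
    hierarchies: tuple[tuple[str, ...], ...] = ()
    poa_exempt: frozenset[str] = frozenset()
    complication_excludable_ccs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        known = set(self.code_to_cc.values())
        for group in self.hierarchies:
            unknown = [cc for cc in group if cc not in known]
            if unknown:
                raise ValueError(
                    f"hierarchy references unknown categories: {unknown}"
                )

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(self.code_to_cc.values())

    @classmethod
    def from_tables(
        cls,
        code_to_cc: pd.DataFrame,
        hierarchy: pd.DataFrame | None = None,
        poa_exempt: pd.DataFrame | None = None,
        excludable_ccs: pd.DataFrame | None = None,
    ) -> "CodeMaps":
        _require(code_to_cc, {"code", "cc"}, "code_to_cc")
        mapping = dict(
            zip(code_to_cc["code"].astype(str), code_to_cc["cc"].astype(str))
        )
        groups: list[tuple[str, ...]] = []
        if hierarchy is not None and len(hierarchy):
            _require(hierarchy, {"group", "rank", "cc"}, "hierarchy")
            for _, grp in hierarchy.sort_values(["group", "rank"]).groupby(
                "group", sort=True
            ):
                groups.append(tuple(grp["cc"].astype(str)))
        exempt: frozenset[str] = frozenset()
        if poa_exempt is not None and len(poa_exempt):
            _require(poa_exempt, {"code"}, "poa_exempt")
            exempt = frozenset(poa_exempt["code"].astype(str))
        excl: frozenset[str] = frozenset()
        if excludable_ccs is not None and len(excludable_ccs):
            _require(excludable_ccs, {"cc"}, "excludable_ccs")
            excl = frozenset(excludable_ccs["cc"].astype(str))
        return cls(
            code_to_cc=mapping,
            hierarchies=tuple(groups),
            poa_exempt=exempt,
            complication_excludable_ccs=excl,
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "CodeMaps":
        """Load the four tables from a directory of CSVs.

        Expects ``code_to_cc.csv`` (required) plus optional
        ``hierarchy.csv``, ``poa_exempt.csv`` and ``excludable_ccs.csv``.
        """
        path = Path(path)
        read = lambda name: (  # noqa: E731
            pd.read_csv(path / name) if (path / name).exists() else None
        )
        cc = read("code_to_cc.csv")
        if cc is None:
            raise FileNotFoundError(f"{path / 'code_to_cc.csv'} not found")
        return cls.from_tables(
            cc,
            read("hierarchy.csv"),
            read("poa_exempt.csv"),
            read("excludable_ccs.csv"),
        )


def load_toy_maps() -> CodeMaps:
    """The packaged synthetic code maps (60 codes, 12 categories, 3
    hierarchy groups) used by the tests and examples."""
    root = resources.files("payrisk").joinpath("data")
    with resources.as_file(root) as p:
        return CodeMaps.from_dir(p)


def _require(df: pd.DataFrame, cols: set[str], name: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{name} table is missing columns {sorted(missing)}")
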