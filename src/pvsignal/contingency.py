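"""Fourfold tables for drug-event disproportionality.

For a target drug versus the rest of the database, each term (a MedDRA
preferred term, or a system organ class via a PT-to-SOC map) gets the
classic 2x2 table::

                 term        other terms
    target        a              b
    other drugs   c              d

The counting unit is the distinct (case, PT) pair: a case reporting the
same PT twice contributes once, a case reporting two PTs contributes two
units.  At SOC level the unit is still the (case, PT) pair, so one case
with two PTs in the same organ class counts twice there - this is what
makes SOC-level percentages sum over total coded reactions rather than
cases.  The grand total N = a+b+c+d is identical for every term at a given
level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd

__all__ = [
    "ContingencyTable",
    "TargetDrug",
    "load_pt_soc_map",
    "case_pt_pairs",
    "build_pt_tables",
    "build_soc_tables",
]

UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class ContingencyTable:
    """One fourfold table; ``level`` is "PT" or "SOC"."""

    term: str
    level: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable":
        """Swap the target and background rows (a<->c, b<->d)."""
        return ContingencyTable(self.term, self.level,
                                self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class TargetDrug:
    """Predicate selecting target-drug reports by name substring and role."""

    names: tuple[str, ...]
    role: str | None = "PS"

    def mask(self, flat: pd.DataFrame) -> pd.Series:
        names = [n.strip().upper() for n in self.names if n.strip()]
        if not names:
            raise ValueError("target drug name list must be nonempty")
        m = pd.Series(False, index=flat.index)
        for n in names:
            m |= flat["normalized_name"].str.contains(n, regex=False)
        if self.role is not None:
            m &= (flat["role"] == self.role).fillna(False).astype(bool)
        return m

    def case_ids(self, flat: pd.DataFrame) -> set[str]:
        return set(flat.loc[self.mask(flat), "caseid"])


def load_pt_soc_map(path: str | Path) -> dict[str, str]:
    """Load a two-column tab-separated ``pt<TAB>soc`` file.

    A PT listed twice with the same SOC is deduplicated silently; two
    different SOCs for one PT is an error naming the PT.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).dropna()
    df["pt"] = df["pt"].str.strip()
    df["soc"] = df["soc"].str.strip()
    df = df.drop_duplicates()
    dup = df["pt"][df["pt"].duplicated()]
    if len(dup):
        raise ValueError("conflicting SOC mapping for PT(s): "
                         + ", ".join(sorted(set(dup))))
    return dict(zip(df["pt"], df["soc"]))


def _normalize_pt(pt: pd.Series) -> pd.Series:
    return pt.str.strip().str.casefold()


def case_pt_pairs(flat: pd.DataFrame) -> pd.DataFrame:
    """Distinct (caseid, pt) pairs with case-folded, trimmed PT strings."""
    pairs = flat.loc[flat["pt"].notna(), ["caseid", "pt"]].copy()
    pairs["pt"] = _normalize_pt(pairs["pt"])
    pairs = pairs[pairs["pt"] != ""]
    return pairs.drop_duplicates().reset_index(drop=True)


def _resolve_target(flat: pd.DataFrame,
                    target: "TargetDrug | Callable | Iterable[str]") -> set[str]:
    if isinstance(target, TargetDrug):
        return target.case_ids(flat)
    if callable(target):
        return set(flat.loc[target(flat), "caseid"])
    return {str(x) for x in target}   # iterable of case ids


def _tables(pairs: pd.DataFrame, target_ids: set[str], term_col: str,
            level: str) -> pd.DataFrame:
    is_t = pairs["caseid"].isin(target_ids)
    total_t = int(is_t.sum())
    total_o = int(len(pairs) - total_t)
    counts = (pairs.assign(_t=is_t)
              .groupby([term_col, "_t"], observed=True).size()
              .unstack("_t", fill_value=0)
              .reindex(columns=[True, False], fill_value=0))
    out = pd.DataFrame({
        "term": counts.index,
        "level": level,
        "a": counts[True].to_numpy(),
        "c": counts[False].to_numpy(),
    })
    out["b"] = total_t - out["a"]
    out["d"] = total_o - out["c"]
    out["N"] = total_t + total_o
    return (out[["term", "level", "a", "b", "c", "d", "N"]]
            .sort_values("term", kind="mergesort").reset_index(drop=True))


def build_pt_tables(flat: pd.DataFrame, target) -> pd.DataFrame:
    """One fourfold table per preferred term (frame with columns
    term/level/a/b/c/d/N).  *target* is a :class:`TargetDrug`, a row
    predicate, or an iterable of case ids."""
    target_ids = _resolve_target(flat, target)
    if not target_ids:
        warnings.warn("target drug matches no cases; returning empty table set")
    return _tables(case_pt_pairs(flat), target_ids, "pt", "PT")


def build_soc_tables(flat: pd.DataFrame, target,
                     pt_soc_map: dict[str, str]) -> pd.DataFrame:
    """Fourfold tables at system-organ-class level.  Each (case, PT) pair
    contributes one unit to its SOC; unmapped PTs are routed to the
    ``UNMAPPED`` bucket with a warning."""
    target_ids = _resolve_target(flat, target)
    pairs = case_pt_pairs(flat)
    lookup = {k.strip().casefold(): v for k, v in pt_soc_map.items()}
    soc = pairs["pt"].map(lookup)
    n_unmapped = int(soc.isna().sum())
    if n_unmapped:
        warnings.warn(f"{n_unmapped} (case, PT) records with unmapped PTs "
                      f"routed to {UNMAPPED!r}")
    pairs = pairs.assign(soc=soc.fillna(UNMAPPED))
    return _tables(pairs, target_ids, "soc", "SOC")


def tables_to_records(tables: pd.DataFrame) -> list[ContingencyTable]:
    """View a table frame as a list of :class:`ContingencyTable`."""
    return [ContingencyTable(r.term, r.level, int(r.a), int(r.b),
                             int(r.c), int(r.d))
            for r in tables.itertuples(index=False)]
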