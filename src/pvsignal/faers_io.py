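"""Reading, cleaning and joining FAERS-style quarterly report tables.

FAERS (the FDA Adverse Event Reporting System) publishes quarterly extracts
as ``$``-delimited ASCII tables: DEMO (one row per report version), DRUG,
REAC (reactions coded as MedDRA preferred terms), THER (therapy dates),
INDI, OUTC, plus quarterly lists of case ids slated for deletion.  This
module parses that dialect into typed :class:`pandas.DataFrame` objects,
consolidates quarters, purges deleted cases, collapses multiple report
versions to one row per case, and joins the result into the flat
(case x drug x reaction) view the signal-detection stages consume.

The dialect accepted here is documented in ``docs/faers_format.md``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SchemaError",
    "Dataset",
    "read_ascii_table",
    "merge_quarters",
    "consolidate_deletions",
    "remove_deleted_cases",
    "deduplicate_cases",
    "clean_dataset",
    "join_case_level",
    "filter_target_drug",
    "validate_counts",
    "load_directory",
]


class SchemaError(ValueError):
    """A table does not conform to the expected FAERS-dialect schema."""


#: required raw columns per table kind
SCHEMAS: dict[str, list[str]] = {
    "demo": ["primaryid", "caseid", "caseversion", "fda_dt", "age", "age_cod",
             "sex", "occp_cod", "occr_country"],
    "drug": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    "reac": ["primaryid", "caseid", "pt"],          # optional: event_dt
    "ther": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
    "indi": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
    "outc": ["primaryid", "caseid", "outc_cod"],
    "deleted": ["caseid"],
}

ROLE_CODES = ("PS", "SS", "C", "I")

# conversion factors to years; unknown codes map to missing.  A blank code
# with a numeric age is treated as years (the common FAERS convention).
AGE_CODE_YEARS = {
    "YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25, "DY": 1.0 / 365.25, "HR": 1.0 / 8766.0,
    "": 1.0,
}

_SEX_MAP = {"M": "male", "F": "female"}
_OCCP_MAP = {"MD": "physician", "HP": "health_professional",
             "PH": "pharmacist", "CN": "consumer", "OT": "other",
             "LW": "other"}


@dataclass
class Dataset:
    """Typed case-level tables: one frame per FAERS entity.

    After :func:`clean_dataset`, ``cases`` holds at most one row per
    ``caseid`` and every ``primaryid`` in the child tables resolves to
    exactly one case row.
    """

    cases: pd.DataFrame
    drugs: pd.DataFrame
    events: pd.DataFrame
    therapies: pd.DataFrame

    def copy(self) -> "Dataset":
        return Dataset(self.cases.copy(), self.drugs.copy(),
                       self.events.copy(), self.therapies.copy())


# ---------------------------------------------------------------------------
# parsing

def parse_faers_dates(raw: pd.Series) -> pd.Series:
    """Parse YYYYMMDD dates; partial dates (YYYY, YYYYMM) are padded to the
    first month/day; anything unparseable becomes NaT."""
    s = raw.fillna("").astype(str).str.strip()
    n = s.str.len()
    s = s.where(n != 4, s + "0101")
    s = s.where(s.str.len() != 6, s + "01")
    s = s.where(s.str.len() == 8, "")
    return pd.to_datetime(s, format="%Y%m%d", errors="coerce")


def _age_to_years(age: pd.Series, code: pd.Series) -> pd.Series:
    value = pd.to_numeric(age.str.strip(), errors="coerce")
    factor = code.fillna("").str.strip().str.upper().map(AGE_CODE_YEARS)
    years = value * factor
    return years.where((years >= 0) & (years <= 130))


def _type_demo(raw: pd.DataFrame) -> pd.DataFrame:
    receipt = parse_faers_dates(raw["fda_dt"])
    sex = raw["sex"].fillna("").str.strip().str.upper().map(_SEX_MAP).fillna("unknown")
    occp = (raw["occp_cod"].fillna("").str.strip().str.upper()
            .map(_OCCP_MAP).fillna("missing"))
    country = raw["occr_country"].fillna("").str.strip()
    out = pd.DataFrame({
        "primaryid": raw["primaryid"].str.strip(),
        "caseid": raw["caseid"].str.strip(),
        "caseversion": pd.to_numeric(raw["caseversion"], errors="coerce")
                         .fillna(0).astype(int).clip(lower=0),
        "receipt_date": receipt,
        "sex": sex,
        "age_years": _age_to_years(raw["age"], raw["age_cod"]),
        "country": country.where(country != "", other=pd.NA),
        "reporter_occupation": occp,
        "report_year": receipt.dt.year.astype("Int64"),
    })
    return out


def _type_drug(raw: pd.DataFrame) -> pd.DataFrame:
    name = raw["drugname"].fillna("").str.strip()
    role = raw["role_cod"].fillna("").str.strip().str.upper()
    bad = ~role.isin(ROLE_CODES)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} drug rows with unknown role code; "
                      "role set to missing")
    return pd.DataFrame({
        "primaryid": raw["primaryid"].str.strip(),
        "caseid": raw["caseid"].str.strip(),
        "drug_seq": pd.to_numeric(raw["drug_seq"], errors="coerce")
                      .fillna(0).astype(int),
        "drug_name": name,
        "normalized_name": name.str.upper(),
        "role": role.where(~bad, other=pd.NA),
    })


def _type_reac(raw: pd.DataFrame) -> pd.DataFrame:
    pt = raw["pt"].fillna("").str.strip()
    event = (parse_faers_dates(raw["event_dt"]) if "event_dt" in raw.columns
             else pd.Series(pd.NaT, index=raw.index))
    out = pd.DataFrame({
        "primaryid": raw["primaryid"].str.strip(),
        "caseid": raw["caseid"].str.strip(),
        "pt": pt,
        "event_date": event,
    })
    return out[out["pt"] != ""].reset_index(drop=True)


def _type_ther(raw: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "primaryid": raw["primaryid"].str.strip(),
        "caseid": raw["caseid"].str.strip(),
        "dsg_drug_seq": pd.to_numeric(raw["dsg_drug_seq"], errors="coerce")
                          .fillna(0).astype(int),
        "start_date": parse_faers_dates(raw["start_dt"]),
    })


def _type_deleted(raw: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({"caseid": raw["caseid"].str.strip()})


def _type_passthrough(raw: pd.DataFrame) -> pd.DataFrame:
    return raw.apply(lambda col: col.fillna("").str.strip())


_TYPERS = {"demo": _type_demo, "drug": _type_drug, "reac": _type_reac,
           "ther": _type_ther, "deleted": _type_deleted,
           "indi": _type_passthrough, "outc": _type_passthrough}


def type_table(raw: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Validate a raw all-string frame against *schema* and return the typed
    frame.  Shared by :func:`read_ascii_table` and the synthetic generator so
    that in-memory and on-disk paths agree."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown table kind {schema!r}")
    missing = [c for c in SCHEMAS[schema] if c not in raw.columns]
    if missing:
        raise SchemaError(f"{schema} table is missing required column(s): "
                          + ", ".join(missing))
    raw = raw.astype(str).replace({"nan": ""})
    return _TYPERS[schema](raw)


def read_ascii_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read one ``$``-delimited FAERS-dialect file into a typed frame.

    Unparseable dates and ages become missing values, never errors.  A
    missing required header column raises :class:`SchemaError` naming it; an
    empty file yields an empty (but correctly typed) frame with a warning.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() == "":
        warnings.warn(f"{path.name}: empty file, returning empty table")
        raw = pd.DataFrame({c: pd.Series(dtype=str) for c in SCHEMAS[schema]})
        return type_table(raw, schema)
    raw = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False)
    raw.columns = [c.strip().lower() for c in raw.columns]
    return type_table(raw, schema)


# ---------------------------------------------------------------------------
# consolidation and cleaning

def merge_quarters(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-quarter tables sharing one schema (row-preserving)."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to merge")
    ref = list(tables[0].columns)
    for t in tables[1:]:
        if list(t.columns) != ref:
            diff = set(ref).symmetric_difference(t.columns)
            raise SchemaError("quarter tables differ in columns: "
                              + ", ".join(sorted(diff)))
    return pd.concat(tables, ignore_index=True)


def consolidate_deletions(lists: Iterable) -> set[str]:
    """Union quarterly deletion lists (frames with a ``caseid`` column, or
    plain iterables of ids) into one set of case ids."""
    out: set[str] = set()
    for item in lists:
        if isinstance(item, pd.DataFrame):
            out.update(item["caseid"].astype(str))
        else:
            out.update(str(x) for x in item)
    return out


def _restrict_children(ds: Dataset, keep_primaryids: pd.Series | set) -> Dataset:
    keep = set(keep_primaryids)
    return Dataset(
        ds.cases,
        ds.drugs[ds.drugs["primaryid"].isin(keep)].reset_index(drop=True),
        ds.events[ds.events["primaryid"].isin(keep)].reset_index(drop=True),
        ds.therapies[ds.therapies["primaryid"].isin(keep)].reset_index(drop=True),
    )


def remove_deleted_cases(ds: Dataset, deleted: Iterable[str]) -> Dataset:
    """Drop every case whose ``caseid`` appears on a deletion list, together
    with its child rows.  Ids absent from the dataset are ignored."""
    dead = {str(x) for x in deleted}
    cases = ds.cases[~ds.cases["caseid"].isin(dead)].reset_index(drop=True)
    out = Dataset(cases, ds.drugs, ds.events, ds.therapies)
    return _restrict_children(out, cases["primaryid"])


def deduplicate_cases(ds: Dataset) -> Dataset:
    """Keep one report per case: highest ``caseversion``, ties broken by
    latest ``receipt_date``, then largest ``primaryid``.  Idempotent and
    independent of input row order."""
    cases = ds.cases.copy()
    pid_num = pd.to_numeric(cases["primaryid"], errors="coerce")
    cases["_pid_num"] = pid_num.fillna(-1)
    cases = cases.sort_values(
        ["caseid", "caseversion", "receipt_date", "_pid_num", "primaryid"],
        kind="mergesort", na_position="first")
    cases = (cases.groupby("caseid", sort=True).tail(1)
             .drop(columns="_pid_num").reset_index(drop=True))
    out = Dataset(cases, ds.drugs, ds.events, ds.therapies)
    return _restrict_children(out, cases["primaryid"])


def clean_dataset(ds: Dataset, deleted: Iterable[str] = ()) -> Dataset:
    """Deletion purge followed by per-case deduplication (idempotent)."""
    return deduplicate_cases(remove_deleted_cases(ds, deleted))


# ---------------------------------------------------------------------------
# joining and selection

def join_case_level(ds: Dataset) -> pd.DataFrame:
    """Flatten a cleaned dataset into one row per (report, drug, reaction).

    Demographics are INNER-joined to drug rows (a case without drug rows is
    dropped); reactions are LEFT-joined (a case without events survives with
    a single all-missing event row); therapy start dates are LEFT-joined on
    the drug sequence number.
    """
    drugs = ds.drugs.drop(columns=["caseid"])
    events = ds.events.drop(columns=["caseid"])
    thers = ds.therapies.drop(columns=["caseid"])
    flat = ds.cases.merge(drugs, on="primaryid", how="inner")
    flat = flat.merge(events, on="primaryid", how="left")
    flat = flat.merge(thers, left_on=["primaryid", "drug_seq"],
                      right_on=["primaryid", "dsg_drug_seq"], how="left")
    return flat.drop(columns=["dsg_drug_seq"]).reset_index(drop=True)


def _match_mask(drugs: pd.DataFrame, names: Iterable[str],
                role: str | None) -> pd.Series:
    names = [str(n).strip().upper() for n in names if str(n).strip()]
    if not names:
        raise ValueError("drug name list must be nonempty")
    mask = pd.Series(False, index=drugs.index)
    for n in names:
        mask |= drugs["normalized_name"].str.contains(n, regex=False)
    if role is not None:
        mask &= (drugs["role"] == role).fillna(False).astype(bool)
    return mask


def target_case_ids(ds: Dataset, names: Iterable[str],
                    role: str | None = "PS") -> set[str]:
    """Case ids having at least one drug row matching any of *names*
    (case-insensitive substring) with the given role (None = any role)."""
    mask = _match_mask(ds.drugs, names, role)
    return set(ds.drugs.loc[mask, "caseid"])


def filter_target_drug(ds: Dataset, names: Iterable[str],
                       role: str | None = "PS") -> Dataset:
    """Restrict the dataset to reports for the target drug (by default with
    the drug in the primary-suspect role).  No match yields an empty
    dataset, not an error."""
    keep = target_case_ids(ds, names, role)
    cases = ds.cases[ds.cases["caseid"].isin(keep)].reset_index(drop=True)
    out = Dataset(cases, ds.drugs, ds.events, ds.therapies)
    return _restrict_children(out, cases["primaryid"])


def validate_counts(ds: Dataset,
                    expected: int | Mapping[str, int] | None = None) -> dict:
    """Compare table sizes against expected counts without aborting.

    *expected* may be a single integer (expected number of cases), a mapping
    of table name to count, or None for an informational report.
    """
    actual = {"cases": len(ds.cases), "drugs": len(ds.drugs),
              "events": len(ds.events), "therapies": len(ds.therapies)}
    if expected is None:
        exp: dict[str, int] = {}
    elif isinstance(expected, Mapping):
        exp = dict(expected)
    else:
        exp = {"cases": int(expected)}
    tables = {}
    ok = True
    for name, count in actual.items():
        entry: dict = {"actual": count}
        if name in exp:
            entry["expected"] = exp[name]
            entry["delta"] = count - exp[name]
            entry["ok"] = entry["delta"] == 0
            ok = ok and entry["ok"]
        tables[name] = entry
    return {"tables": tables, "ok": ok, "informational": not exp}


# ---------------------------------------------------------------------------
# directory loading

def load_directory(path: str | Path) -> tuple[Dataset, set[str]]:
    """Load every quarterly file in *path* (``demo_*.txt`` etc.), merge the
    quarters and return the raw dataset plus the consolidated deletion set."""
    path = Path(path)

    def _read(kind: str) -> pd.DataFrame:
        files = sorted(path.glob(f"{kind}_*.txt"))
        if not files:
            raw = pd.DataFrame({c: pd.Series(dtype=str) for c in SCHEMAS[kind]})
            return type_table(raw, kind)
        return merge_quarters([read_ascii_table(f, kind) for f in files])

    ds = Dataset(_read("demo"), _read("drug"), _read("reac"), _read("ther"))
    deleted = consolidate_deletions(
        read_ascii_table(f, "deleted") for f in sorted(path.glob("deleted_*.txt")))
    return ds, deleted
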