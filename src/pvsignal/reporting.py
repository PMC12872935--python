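"""Descriptive cohort summaries and reproducible report bundles.

Percentages follow publication arithmetic: 100 * count / total, rounded
half-up to one decimal (so 513 of 1,082 prints as 47.4).  Age bands use
left-closed intervals [0, 18), [18, 60), [60, 80), [80, inf) to keep the
conventional "18-60 / 60-80" labels non-overlapping.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .faers_io import Dataset

__all__ = ["percentage", "describe_cohort", "CohortSummary", "build_report"]

DEFAULT_AGE_EDGES = (0.0, 18.0, 60.0, 80.0, math.inf)


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """100*count/total rounded half-up (not banker's) at *decimals*."""
    from decimal import Decimal, ROUND_HALF_UP

    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(count) * 100 / Decimal(total))
                 .quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Counts and percentages per characteristic; counts within each block
    sum to the case total."""

    n_cases: int
    sex: pd.DataFrame
    age_band: pd.DataFrame
    country: pd.DataFrame
    reporter: pd.DataFrame
    report_year: pd.DataFrame

    def blocks(self) -> dict[str, pd.DataFrame]:
        return {"sex": self.sex, "age_band": self.age_band,
                "country": self.country, "reporter": self.reporter,
                "report_year": self.report_year}


def _block(labels: pd.Series, total: int, order=None) -> pd.DataFrame:
    counts = labels.value_counts()
    if order is not None:
        counts = counts.reindex(order, fill_value=0)
    return pd.DataFrame({
        "category": counts.index.astype(str),
        "count": counts.to_numpy(int),
        "pct": [percentage(int(c), total) for c in counts.to_numpy(int)],
    })


def describe_cohort(ds: Dataset, age_edges=DEFAULT_AGE_EDGES,
                    top_k: int = 5) -> CohortSummary:
    """Table-style descriptive summary of a cleaned, target-filtered cohort."""
    cases = ds.cases
    total = len(cases)
    if total == 0:
        raise ValueError("empty dataset")

    edges = list(age_edges)
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == 0:
            labels.append(f"<{hi:g}")
        elif math.isinf(hi):
            labels.append(f">={lo:g}")
        else:
            labels.append(f"{lo:g}-{hi:g}")
    band = pd.cut(cases["age_years"], bins=edges, labels=labels,
                  right=False, include_lowest=True)
    band = band.cat.add_categories(["missing"]).fillna("missing")

    country = cases["country"].fillna("missing")
    top = country.value_counts().index[:top_k]
    country_block = _block(country[country.isin(top)], total)
    n_other = int((~country.isin(top)).sum())
    if n_other:
        country_block = pd.concat([country_block, pd.DataFrame(
            [{"category": "other", "count": n_other,
              "pct": percentage(n_other, total)}])], ignore_index=True)

    year = cases["report_year"].astype("Int64")
    year_lab = year.astype(str).where(year.notna(), "missing")

    return CohortSummary(
        n_cases=total,
        sex=_block(cases["sex"], total, order=["male", "female", "unknown"]),
        age_band=_block(band, total, order=labels + ["missing"]),
        country=country_block,
        reporter=_block(cases["reporter_occupation"], total),
        report_year=_block(year_lab, total,
                           order=sorted(year_lab.unique())),
    )


# ---------------------------------------------------------------------------
# report bundle

REQUIRED_STAGES = ("validation", "cohort", "signals_pt", "signals_soc",
                   "onset", "subgroups", "regression")


def _write_artifact(path: Path, obj) -> None:
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path.with_suffix(".csv"), index=False,
                   lineterminator="\n", float_format="%.10g")
    else:
        path.with_suffix(".json").write_text(
            json.dumps(obj, indent=1, sort_keys=True, default=str) + "\n")


def build_report(out_dir: str | Path, artifacts: dict, config: dict,
                 seed: int, required=REQUIRED_STAGES) -> dict:
    """Write every stage output plus the run config, seed and a manifest
    with per-file SHA-256 digests.  Bitwise-stable for identical inputs.
    A missing required stage raises an error listing the gap."""
    missing = [k for k in required if k not in artifacts]
    if missing:
        raise ValueError("missing stage output(s): " + ", ".join(missing))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, obj in sorted(artifacts.items()):
        _write_artifact(out_dir / name, obj)
    (out_dir / "run_config.json").write_text(
        json.dumps({"config": config, "seed": seed}, indent=1,
                   sort_keys=True, default=str) + "\n")
    files = sorted(p for p in out_dir.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": seed,
        "files": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                  for p in files},
    }
    manifest["bundle_hash"] = hashlib.sha256(
        json.dumps(manifest["files"], sort_keys=True).encode()).hexdigest()
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
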