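"""Subgroup, period and regimen comparisons within target-drug reports.

Each comparison contrasts two strata of the target drug's own reports (age
bands, sex, early vs late reporting period, or monotherapy vs a
comedication regimen).  Per term, the 2x2 stratum-by-term table of
(case, term) records gives:

* ``effect_log2`` - the log2 odds ratio of the term appearing in stratum A
  versus stratum B (a volcano-plot x-axis; positive = relatively more
  reported in A), with a +0.5 continuity correction on zero cells;
* ``p_value`` - the uncorrected chi-square test when every expected cell
  is >= 5, otherwise Fisher's exact test (a volcano-plot y-axis via
  -log10 p).

No multiplicity adjustment gates the ``significant`` flag; a Bonferroni
column is emitted for the reader.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .contingency import TargetDrug, case_pt_pairs

__all__ = [
    "compare_strata",
    "compare_periods",
    "compare_regimens",
    "age_strata",
    "sex_strata",
]


def _term_pairs(flat: pd.DataFrame, target, soc_map=None) -> pd.DataFrame:
    if isinstance(target, TargetDrug):
        ids = target.case_ids(flat)
        flat = flat[flat["caseid"].isin(ids)]
    pairs = case_pt_pairs(flat)
    if soc_map is not None:
        lookup = {k.strip().casefold(): v for k, v in soc_map.items()}
        pairs = pairs.assign(term=pairs["pt"].map(lookup).fillna("UNMAPPED"))
    else:
        pairs = pairs.assign(term=pairs["pt"])
    return pairs[["caseid", "term"]]


def _two_by_two_p(a: int, b: int, c: int, d: int) -> float:
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    if n == 0 or table.sum(0).min() == 0 or table.sum(1).min() == 0:
        return 1.0
    expected = np.outer(table.sum(1), table.sum(0)) / n
    if expected.min() >= 5:
        chi2 = ((table - expected) ** 2 / expected).sum()
        return float(stats.chi2.sf(chi2, df=1))
    return float(stats.fisher_exact([[a, b], [c, d]])[1])


def compare_strata(flat: pd.DataFrame, case_strata: pd.Series, target=None,
                   min_count: int = 3, alpha: float = 0.05,
                   soc_map: dict | None = None) -> pd.DataFrame:
    """Per-term A-vs-B comparison of (case, term) records.

    *case_strata* maps caseid to the label "A" or "B" (cases absent from
    the index, or with other labels, are excluded, which is how missing
    ages leave the age subgroups).  Raises if either stratum is empty.
    """
    pairs = _term_pairs(flat, target, soc_map)
    lab = pairs["caseid"].map(case_strata)
    pairs = pairs.assign(stratum=lab)[lab.isin(["A", "B"])]
    tot = pairs.groupby("stratum").size().reindex(["A", "B"], fill_value=0)
    if tot.min() == 0:
        raise ValueError("degenerate stratifier: one stratum has no records")
    counts = (pairs.groupby(["term", "stratum"], observed=True).size()
              .unstack("stratum", fill_value=0)
              .reindex(columns=["A", "B"], fill_value=0))
    rows = []
    for term, row in counts.iterrows():
        n_a, n_b = int(row["A"]), int(row["B"])
        if n_a + n_b < min_count:
            continue
        other_a = int(tot["A"] - n_a)
        other_b = int(tot["B"] - n_b)
        cells = np.array([n_a, other_a, n_b, other_b], dtype=float)
        if cells.min() == 0:
            cells = cells + 0.5
        effect = float(np.log2(cells[0] * cells[3] / (cells[1] * cells[2])))
        p = _two_by_two_p(n_a, other_a, n_b, other_b)
        rows.append({"term": term, "n_in_A": n_a, "n_other_A": other_a,
                     "n_in_B": n_b, "n_other_B": other_b,
                     "effect_log2": effect, "p_value": p,
                     "significant": p < alpha and effect != 0.0})
    out = pd.DataFrame(rows, columns=["term", "n_in_A", "n_other_A", "n_in_B",
                                      "n_other_B", "effect_log2", "p_value",
                                      "significant"])
    if len(out):
        out["p_bonferroni"] = np.minimum(out["p_value"] * len(out), 1.0)
        out = out.sort_values("term", kind="mergesort").reset_index(drop=True)
    else:
        out["p_bonferroni"] = pd.Series(dtype=float)
    return out


def age_strata(cases: pd.DataFrame, young: tuple[float, float] = (18, 65),
               old_min: float = 65) -> pd.Series:
    """A = the younger band [lo, hi), B = ages >= old_min; missing ages and
    children fall in neither stratum.  Defaults follow the common 18-64 vs
    65-and-over split; band edges are configurable."""
    age = cases.set_index("caseid")["age_years"]
    lab = pd.Series("", index=age.index, dtype=object)
    lab[(age >= young[0]) & (age < young[1])] = "A"
    lab[age >= old_min] = "B"
    return lab


def sex_strata(cases: pd.DataFrame) -> pd.Series:
    """A = male, B = female; unknown sex excluded."""
    sex = cases.set_index("caseid")["sex"]
    return sex.map({"male": "A", "female": "B"}).fillna("")


def compare_periods(flat: pd.DataFrame, target=None,
                    cutoff_year: int = 2020, **kw) -> pd.DataFrame:
    """Early (report year < cutoff, stratum A) versus late (>= cutoff, B)."""
    years = flat.drop_duplicates("caseid").set_index("caseid")["report_year"]
    lab = pd.Series("", index=years.index, dtype=object)
    lab[(years < cutoff_year).fillna(False).astype(bool)] = "A"
    lab[(years >= cutoff_year).fillna(False).astype(bool)] = "B"
    return compare_strata(flat, lab, target=target, **kw)


def compare_regimens(flat: pd.DataFrame, comedication: str, target,
                     soc_map: dict, min_count: int = 3) -> pd.DataFrame:
    """Monotherapy vs combination regimen at system-organ-class level.

    Stratum A = target-drug cases also reporting *comedication* (any role),
    B = target-drug cases without it.  Emits a forest-plot-ready frame with
    the odds ratio and its log-normal 95% interval per SOC.
    """
    if isinstance(target, TargetDrug):
        ids = target.case_ids(flat)
    else:
        ids = {str(x) for x in target}
    sub = flat[flat["caseid"].isin(ids)]
    com = TargetDrug((comedication,), role=None)
    with_com = com.case_ids(sub)
    if not with_com:
        warnings.warn(f"comedication {comedication!r} absent from "
                      "target-drug cases; empty comparison")
        return pd.DataFrame(columns=["term", "n_in_A", "n_other_A", "n_in_B",
                                     "n_other_B", "or_", "or_lo", "or_hi",
                                     "effect_log2", "p_value", "significant"])
    lab = pd.Series("B", index=pd.Index(sorted(ids), name="caseid"), dtype=object)
    lab[lab.index.isin(with_com)] = "A"
    out = compare_strata(sub, lab, target=None, min_count=min_count,
                         soc_map=soc_map)
    cells = out[["n_in_A", "n_other_A", "n_in_B", "n_other_B"]].to_numpy(float)
    zero = cells.min(axis=1) == 0
    cells[zero] += 0.5
    or_ = cells[:, 0] * cells[:, 3] / (cells[:, 1] * cells[:, 2])
    se = np.sqrt((1 / cells).sum(axis=1))
    out["or_"] = or_
    out["or_lo"] = or_ * np.exp(-1.96 * se)
    out["or_hi"] = or_ * np.exp(1.96 * se)
    return out
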