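"""Four-algorithm disproportionality screening.

Given a fourfold table (a, b, c, d) with grand total N, the four classic
signal-detection statistics are computed in their closed printed forms:

* ROR  = ad/(bc), with the log-normal 95% interval
  exp(ln ROR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d));
* PRR  = a(c+d) / (c(a+b)), with the uncorrected chi-square
  (ad - bc)^2 N / ((a+b)(c+d)(a+c)(b+d));
* IC   = log2(a N / ((a+b)(a+c))) in bits, interval IC +/- 2 sd(IC) with the
  delta-method sd(IC) = sqrt(1/a + 1/b + 1/c + 1/d) / ln 2;
* EBGM = a N / ((a+c)(a+b)), with the same log-normal 95% interval as ROR.

Note that this EBGM is the simplified closed-form observed/expected ratio
(identical to 2**IC by construction), not a shrinkage posterior from a full
gamma-Poisson fit; the matching thresholds are the ones conventionally used
with it.  A term is a combined signal when all four per-algorithm criteria
hold: ROR lower bound > 1 with n >= 3; PRR >= 2 with chi-square >= 4 and
n >= 3; IC025 > 0; EBGM05 > 2 (n is the observed count a).

Tables containing a zero cell are non-evaluable by default (their
statistics are missing and their flags false); the Haldane-Anscombe +0.5
correction is available behind ``zero_cell="haldane"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .contingency import ContingencyTable

__all__ = [
    "SignalResult",
    "ror",
    "prr",
    "information_component",
    "ebgm",
    "signal_result",
    "evaluate_thresholds",
    "compute_signal_frame",
    "screen",
]

_LN2 = math.log(2.0)
_Z = 1.96

STAT_COLUMNS = ["ror", "ror_lo", "ror_hi", "prr", "chi2", "ic", "ic025",
                "ebgm", "ebgm05", "ebgm95"]
FLAG_COLUMNS = ["flag_ror", "flag_prr", "flag_ic", "flag_ebgm", "flag_all4"]


@dataclass(frozen=True)
class SignalResult:
    """Per-term statistics, interval bounds and threshold flags."""

    term: str
    level: str
    n: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    ebgm95: float
    flag_ror: bool = False
    flag_prr: bool = False
    flag_ic: bool = False
    flag_ebgm: bool = False
    flag_all4: bool = False


def _cells(t: ContingencyTable, zero_cell: str) -> tuple[float, float, float, float]:
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if zero_cell == "haldane" and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a, b, c, d


def _se_log(a, b, c, d):
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def ror(t: ContingencyTable, zero_cell: str = "na") -> tuple[float, float, float]:
    """Reporting odds ratio with its log-normal 95% interval; NaNs when the
    table has a zero cell (non-evaluable)."""
    a, b, c, d = _cells(t, zero_cell)
    if min(a, b, c, d) == 0:
        return (math.nan,) * 3
    est = a * d / (b * c)
    half = _Z * _se_log(a, b, c, d)
    return est, est * math.exp(-half), est * math.exp(half)


def prr(t: ContingencyTable, zero_cell: str = "na") -> tuple[float, float]:
    """Proportional reporting ratio and the uncorrected chi-square."""
    a, b, c, d = _cells(t, zero_cell)
    if min(a, b, c, d) == 0:
        return math.nan, math.nan
    n = a + b + c + d
    est = a * (c + d) / (c * (a + b))
    chi2 = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
    return est, chi2


def information_component(t: ContingencyTable,
                          zero_cell: str = "na") -> tuple[float, float]:
    """Information component (bits) and its lower bound IC - 2 sd(IC)."""
    a, b, c, d = _cells(t, zero_cell)
    if min(a, b, c, d) == 0:
        return math.nan, math.nan
    n = a + b + c + d
    ic = math.log2(a * n / ((a + b) * (a + c)))
    sd = _se_log(a, b, c, d) / _LN2
    return ic, ic - 2 * sd


def ebgm(t: ContingencyTable, zero_cell: str = "na") -> tuple[float, float, float]:
    """Closed-form observed/expected ratio with its log-normal interval."""
    a, b, c, d = _cells(t, zero_cell)
    if min(a, b, c, d) == 0:
        return (math.nan,) * 3
    n = a + b + c + d
    est = a * n / ((a + c) * (a + b))
    half = _Z * _se_log(a, b, c, d)
    return est, est * math.exp(-half), est * math.exp(half)


def signal_result(t: ContingencyTable, zero_cell: str = "na") -> SignalResult:
    """All four statistics for one table, with threshold flags applied."""
    r, r_lo, r_hi = ror(t, zero_cell)
    p, chi2 = prr(t, zero_cell)
    ic, ic025 = information_component(t, zero_cell)
    e, e05, e95 = ebgm(t, zero_cell)
    res = SignalResult(t.term, t.level, int(t.a), r, r_lo, r_hi,
                       p, chi2, ic, ic025, e, e05, e95)
    return evaluate_thresholds(res)


def evaluate_thresholds(r: SignalResult) -> SignalResult:
    """Apply the per-algorithm criteria (missing statistics never flag).

    Boundary semantics: PRR >= 2, chi-square >= 4 and n >= 3 are inclusive;
    IC025 > 0 and EBGM05 > 2 and ROR lower bound > 1 are strict.
    """
    def _ok(x):  # NaN-safe comparison
        return (not math.isnan(x)) if isinstance(x, float) else True

    f_ror = _ok(r.ror_lo) and r.ror_lo > 1 and r.n >= 3
    f_prr = _ok(r.prr) and _ok(r.chi2) and r.prr >= 2 and r.chi2 >= 4 and r.n >= 3
    f_ic = _ok(r.ic025) and r.ic025 > 0
    f_ebgm = _ok(r.ebgm05) and r.ebgm05 > 2
    return replace(r, flag_ror=f_ror, flag_prr=f_prr, flag_ic=f_ic,
                   flag_ebgm=f_ebgm,
                   flag_all4=f_ror and f_prr and f_ic and f_ebgm)


# ---------------------------------------------------------------------------
# vectorised screening over a table frame

def compute_signal_frame(tables: pd.DataFrame,
                         zero_cell: str = "na") -> pd.DataFrame:
    """Vectorised statistics + flags for a term/level/a/b/c/d/N frame."""
    a = tables["a"].to_numpy(float)
    b = tables["b"].to_numpy(float)
    c = tables["c"].to_numpy(float)
    d = tables["d"].to_numpy(float)
    if zero_cell == "haldane":
        zero = np.minimum.reduce([a, b, c, d]) == 0
        a, b, c, d = (x + 0.5 * zero for x in (a, b, c, d))
    evaluable = np.minimum.reduce([a, b, c, d]) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        n_tot = a + b + c + d
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ror_ = a * d / (b * c)
        prr_ = a * (c + d) / (c * (a + b))
        chi2 = (a * d - b * c) ** 2 * n_tot / ((a + b) * (c + d) * (a + c) * (b + d))
        ebgm_ = a * n_tot / ((a + c) * (a + b))
        ic = np.log2(ebgm_)
    out = pd.DataFrame({
        "term": tables["term"].to_numpy(),
        "level": tables["level"].to_numpy(),
        "n": tables["a"].to_numpy(int),
        "ror": ror_, "ror_lo": ror_ * np.exp(-_Z * se),
        "ror_hi": ror_ * np.exp(_Z * se),
        "prr": prr_, "chi2": chi2,
        "ic": ic, "ic025": ic - 2 * se / _LN2,
        "ebgm": ebgm_, "ebgm05": ebgm_ * np.exp(-_Z * se),
        "ebgm95": ebgm_ * np.exp(_Z * se),
    })
    out.loc[~evaluable, STAT_COLUMNS] = np.nan
    ev = evaluable
    out["flag_ror"] = ev & (out["ror_lo"] > 1) & (out["n"] >= 3)
    out["flag_prr"] = ev & (out["prr"] >= 2) & (out["chi2"] >= 4) & (out["n"] >= 3)
    out["flag_ic"] = ev & (out["ic025"] > 0)
    out["flag_ebgm"] = ev & (out["ebgm05"] > 2)
    out["flag_all4"] = (out["flag_ror"] & out["flag_prr"]
                        & out["flag_ic"] & out["flag_ebgm"])
    return out


def screen(tables: pd.DataFrame, zero_cell: str = "na",
           sort_by: str = "n") -> pd.DataFrame:
    """Ranked signal table: one row per term with a >= 1 report, sorted by
    *sort_by* (descending, default the report count) with the term label as
    the deterministic tie-break."""
    tables = tables[tables["a"] > 0]
    out = compute_signal_frame(tables, zero_cell=zero_cell)
    return (out.sort_values([sort_by, "term"], ascending=[False, True],
                            kind="mergesort", na_position="last")
            .reset_index(drop=True))


def format_signal_table(results: pd.DataFrame,
                        n_total: int | None = None) -> pd.DataFrame:
    """Publication-style strings: "ROR (95% CI)", "PRR(chi2)", etc.

    *n_total* is the denominator for the case percentage (the cohort's
    total (case, term) records, i.e. a + b); defaults to the sum of the
    counts in *results*, which is only right for a complete table.
    """
    def _f(x, nd=2):
        return "NE" if pd.isna(x) else f"{x:.{nd}f}"

    n_target = int(n_total) if n_total is not None else results["n"].sum()
    return pd.DataFrame({
        "term": results["term"],
        "case (%)": [f"{n} ({100 * n / max(n_target, 1):.1f}%)"
                     for n in results["n"]],
        "ROR (95% CI)": [f"{_f(r)}({_f(lo)}-{_f(hi)})" for r, lo, hi in
                         zip(results["ror"], results["ror_lo"], results["ror_hi"])],
        "PRR(chi2)": [f"{_f(p)}({_f(x)})" for p, x in
                      zip(results["prr"], results["chi2"])],
        "EBGM(EBGM05)": [f"{_f(e)}({_f(lo)})" for e, lo in
                         zip(results["ebgm"], results["ebgm05"])],
        "IC(IC025)": [f"{_f(i)}({_f(lo, 1)})" for i, lo in
                      zip(results["ic"], results["ic025"])],
        "signal": results["flag_all4"].map({True: "*", False: ""}),
    })
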