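"""Covariate-adjusted reporting odds ratios via logistic regression.

Crude disproportionality confounds drug effects with the clinical context
in which the drug is given ("confounding by indication").  To separate a
combination-therapy signal from baseline severity, the outcome (a target
preferred term present in the case) is modelled at case level as a
function of the exposure (a comedication present in the case) adjusted for
age, sex, reporting year and concomitant nephrotoxic agents as severity
proxies.  exp(coefficient) on the exposure is the adjusted reporting odds
ratio (aROR) with its Wald 95% interval.

Design choices: age enters linearly per 10 years; reporting year as a
linear trend centred at the earliest year; sex is reference-coded against
female (with a separate indicator for unknown sex); missing age is handled
by complete-case analysis by default, or a missing-indicator policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .contingency import TargetDrug

__all__ = [
    "LogisticFit",
    "build_records",
    "fit_logistic",
    "DEFAULT_NEPHROTOXINS",
]

DEFAULT_NEPHROTOXINS = ("VANCOMYCIN", "GENTAMICIN", "TOBRAMYCIN", "AMIKACIN")

SEPARATION_LOGIT = 15.0


@dataclass
class LogisticFit:
    """Coefficients, Wald intervals and odds ratios from one model fit."""

    params: pd.Series
    bse: pd.Series
    p_values: pd.Series
    or_: pd.Series
    or_lo: pd.Series
    or_hi: pd.Series
    loglik: float
    loglik_null: float
    n_used: int
    converged: bool
    separation_detected: bool

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse,
                             "or": self.or_, "or_lo": self.or_lo,
                             "or_hi": self.or_hi, "p": self.p_values})


def _cases_with_drug(flat: pd.DataFrame, names) -> set[str]:
    return TargetDrug(tuple(names), role=None).case_ids(flat)


def build_records(flat: pd.DataFrame, outcome_pt: str, exposure_drug: str,
                  nephrotoxin_names=DEFAULT_NEPHROTOXINS) -> pd.DataFrame:
    """One record per case of an (already target-filtered) flat table.

    outcome = the outcome PT present among the case's reactions (exact
    match after case-folding/trimming); exposure = the comedication present
    among the case's drugs in any role; nephrotoxin = any listed agent
    present.  Raises if the outcome prevalence is 0 or 1.
    """
    key = outcome_pt.strip().casefold()
    pts = flat.loc[flat["pt"].notna(), ["caseid", "pt"]].copy()
    pts["pt"] = pts["pt"].str.strip().str.casefold()
    with_outcome = set(pts.loc[pts["pt"] == key, "caseid"])
    exposed = _cases_with_drug(flat, [exposure_drug])
    neph = _cases_with_drug(flat, nephrotoxin_names)

    cases = flat.drop_duplicates("caseid")
    rec = pd.DataFrame({
        "caseid": cases["caseid"].to_numpy(),
        "outcome": cases["caseid"].isin(with_outcome).astype(int).to_numpy(),
        "exposure": cases["caseid"].isin(exposed).astype(int).to_numpy(),
        "age_years": cases["age_years"].to_numpy(float),
        "sex": cases["sex"].to_numpy(),
        "report_year": cases["report_year"].to_numpy(dtype=float,
                                                     na_value=np.nan),
        "nephrotoxin": cases["caseid"].isin(neph).astype(int).to_numpy(),
    })
    prevalence = rec["outcome"].mean()
    if prevalence in (0.0, 1.0):
        raise ValueError(f"outcome {outcome_pt!r} has prevalence "
                         f"{prevalence:g}; model undefined")
    return rec


def _design(records: pd.DataFrame, covariates: bool,
            age_policy: str) -> tuple[pd.Series, pd.DataFrame]:
    rec = records.copy()
    if not covariates:
        X = pd.DataFrame({"exposure": rec["exposure"].astype(float)})
    else:
        rec = rec[rec["report_year"].notna()]
        if age_policy == "complete":
            rec = rec[rec["age_years"].notna()]
            age10 = (rec["age_years"] - 55.0) / 10.0
            age_cols = {"age_per10": age10}
        elif age_policy == "indicator":
            missing = rec["age_years"].isna()
            age10 = ((rec["age_years"].fillna(55.0)) - 55.0) / 10.0
            age_cols = {"age_per10": age10,
                        "age_missing": missing.astype(float)}
        else:
            raise ValueError(f"unknown age policy {age_policy!r}")
        year0 = rec["report_year"].min()
        X = pd.DataFrame({
            "exposure": rec["exposure"].astype(float),
            **age_cols,
            "sex_male": (rec["sex"] == "male").astype(float),
            "sex_unknown": (rec["sex"] == "unknown").astype(float),
            "year_trend": rec["report_year"].astype(float) - year0,
            "nephrotoxin": rec["nephrotoxin"].astype(float),
        }, index=rec.index)
        # the unknown-sex indicator is structural: absent levels are simply
        # dropped rather than reported as collinear
        if X["sex_unknown"].nunique() <= 1:
            X = X.drop(columns="sex_unknown")
    y = rec["outcome"].astype(float)
    return y, sm.add_constant(X, has_constant="add")


def fit_logistic(records: pd.DataFrame, covariates: bool = True,
                 age_policy: str = "complete") -> LogisticFit:
    """Newton-Raphson logistic fit with Wald inference.

    With ``covariates=False`` only the exposure enters, and exp(coef)
    reproduces the closed-form fourfold-table odds ratio exactly.
    Quasi-separation (any |coefficient| above 15 on the logit scale) is
    flagged, not raised; a rank-deficient design raises an error naming a
    collinear column.
    """
    y, X = _design(records, covariates, age_policy)
    if y.mean() in (0.0, 1.0):
        raise ValueError("outcome has no variation in the analysis sample")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        for col in X.columns[::-1]:
            if np.linalg.matrix_rank(X.drop(columns=col).to_numpy()) == rank:
                raise ValueError(f"design matrix is rank deficient; "
                                 f"column {col!r} is collinear")
        raise ValueError("design matrix is rank deficient")
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y.to_numpy(), X.to_numpy())
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            # separated likelihoods have no finite Newton optimum; a capped
            # quasi-Newton pass still yields a reportable (flagged) iterate
            res = model.fit(method="bfgs", maxiter=200, disp=0)
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    pvals = pd.Series(res.pvalues, index=X.columns)
    sep = bool((params.abs() > SEPARATION_LOGIT).any())
    if sep:
        warnings.warn("quasi-separation detected: a coefficient exceeds "
                      f"{SEPARATION_LOGIT} on the logit scale")
    with np.errstate(over="ignore"):   # separated fits overflow to inf OR
        or_, or_lo, or_hi = (np.exp(params), np.exp(params - 1.96 * bse),
                             np.exp(params + 1.96 * bse))
    return LogisticFit(
        params=params, bse=bse, p_values=pvals,
        or_=or_, or_lo=or_lo, or_hi=or_hi,
        loglik=float(res.llf), loglik_null=float(res.llnull),
        n_used=int(len(y)), converged=bool(res.mle_retvals["converged"]),
        separation_detected=sep)
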