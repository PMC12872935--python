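"""Time-to-onset analysis of adverse events.

Onset latency is the number of days from the start of target-drug therapy
to the event, with same-day onset mapped to 1 day so that day-granular data
stay strictly positive.  The latency sample is summarised (median and IQR
by linear interpolation between order statistics, counts per half-open day
bin) and fitted with a Weibull model by maximum likelihood.  The shape
parameter beta diagnoses the hazard trend: beta < 1 with its whole
confidence interval below 1 indicates a decreasing risk of new events over
time (an "early failure" profile), beta > 1 an increasing one.

The two-parameter fit (location fixed at zero) is the default; the
three-parameter variant profiles the location over [0, min(days)) and is
offered for exploratory use only, because with day-granular, tied data a
free location makes the likelihood ill-behaved when the shape is below 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "OnsetSample",
    "WeibullFit",
    "compute_onsets",
    "summarize_onsets",
    "fit_weibull",
    "hazard_label",
]

DEFAULT_BIN_EDGES = (1, 6, 11, 16, 21, 26, 31, math.inf)


@dataclass
class OnsetSample:
    """Retained onset latencies (days >= 1) plus exclusion tallies."""

    days: np.ndarray
    n_excluded_missing: int = 0
    n_excluded_negative: int = 0

    def __len__(self) -> int:
        return len(self.days)


@dataclass
class WeibullFit:
    shape: float
    scale: float
    location: float
    shape_ci: tuple[float, float]
    scale_ci: tuple[float, float]
    loglik: float
    converged: bool
    n: int


def compute_onsets(flat: pd.DataFrame, target) -> OnsetSample:
    """Onset latency per distinct (case, PT) record of target-drug cases.

    Latency = event date - earliest target-drug therapy start date + 1 day.
    Records missing either date are excluded and counted; negative
    latencies (event strictly before therapy start) likewise.
    """
    from .contingency import TargetDrug

    if isinstance(target, TargetDrug):
        t_mask = target.mask(flat)
    elif callable(target):
        t_mask = target(flat)
    else:
        t_mask = flat["caseid"].isin({str(x) for x in target}) \
            & (flat["role"] == "PS").fillna(False).astype(bool)

    starts = (flat.loc[t_mask & flat["start_date"].notna(),
                       ["caseid", "start_date"]]
              .groupby("caseid")["start_date"].min())
    target_cases = set(flat.loc[t_mask, "caseid"])
    recs = flat.loc[flat["caseid"].isin(target_cases) & flat["pt"].notna(),
                    ["caseid", "pt", "event_date"]].drop_duplicates(
        subset=["caseid", "pt"])
    start = recs["caseid"].map(starts)
    missing = recs["event_date"].isna() | start.isna()
    delta = (recs["event_date"] - start).dt.days + 1
    negative = (~missing) & (delta < 1)
    keep = delta[~missing & ~negative].to_numpy(dtype=float)
    return OnsetSample(days=keep.astype(int),
                       n_excluded_missing=int(missing.sum()),
                       n_excluded_negative=int(negative.sum()))


def summarize_onsets(sample: OnsetSample | np.ndarray,
                     bin_edges=DEFAULT_BIN_EDGES) -> dict:
    """Median, quartiles (linear interpolation between order statistics)
    and counts per half-open bin [e_i, e_{i+1})."""
    days = np.asarray(sample.days if isinstance(sample, OnsetSample) else sample,
                      dtype=float)
    if days.size == 0:
        raise ValueError("empty onset sample")
    q1, med, q3 = np.percentile(days, [25, 50, 75])
    edges = np.asarray(bin_edges, dtype=float)
    counts = [int(((days >= lo) & (days < hi)).sum())
              for lo, hi in zip(edges[:-1], edges[1:])]
    labels = [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    return {"n": int(days.size), "median": float(med),
            "q1": float(q1), "q3": float(q3),
            "bins": dict(zip(labels, counts))}


# ---------------------------------------------------------------------------
# Weibull maximum likelihood

def _profile_score(k: float, x: np.ndarray, logx: np.ndarray) -> float:
    # derivative of the profile log-likelihood in the shape k, with the
    # scale concentrated out (lambda^k = mean(x^k))
    xk = np.power(x, k)
    return 1.0 / k + logx.mean() - float((xk * logx).sum() / xk.sum())


def _loglik(k: float, lam: float, x: np.ndarray) -> float:
    z = x / lam
    return float(np.sum(np.log(k / lam) + (k - 1) * np.log(z) - z ** k))


def _fit_two_parameter(x: np.ndarray) -> tuple[float, float, bool]:
    logx = np.log(x)
    if np.allclose(logx, logx[0]):
        # degenerate all-equal sample: likelihood maximised as shape -> inf
        return math.inf, float(x[0]), False
    lo, hi = 1e-3, 1.0
    while _profile_score(hi, x, logx) > 0 and hi < 1e3:
        hi *= 2.0
    try:
        k = optimize.brentq(_profile_score, lo, hi, args=(x, logx),
                            xtol=1e-12, rtol=1e-12)
        ok = True
    except ValueError:
        k, ok = hi, False
    lam = float(np.power(np.power(x, k).mean(), 1.0 / k))
    return float(k), lam, ok


def _hessian_log_scale(k: float, lam: float, x: np.ndarray) -> np.ndarray:
    # numerical observed information in (log shape, log scale)
    h = 1e-5

    def f(u, v):
        return _loglik(math.exp(u), math.exp(v), x)

    u0, v0 = math.log(k), math.log(lam)
    H = np.empty((2, 2))
    H[0, 0] = (f(u0 + h, v0) - 2 * f(u0, v0) + f(u0 - h, v0)) / h ** 2
    H[1, 1] = (f(u0, v0 + h) - 2 * f(u0, v0) + f(u0, v0 - h)) / h ** 2
    H[0, 1] = H[1, 0] = (f(u0 + h, v0 + h) - f(u0 + h, v0 - h)
                         - f(u0 - h, v0 + h) + f(u0 - h, v0 - h)) / (4 * h ** 2)
    return -H


def fit_weibull(sample: OnsetSample | np.ndarray,
                three_parameter: bool = False) -> WeibullFit:
    """Maximum-likelihood Weibull fit with Wald 95% intervals.

    Intervals come from the observed information on the log-parameter
    scale (so they respect positivity).  With ``three_parameter=True`` the
    location is profiled over [0, min(sample)); by default it is fixed at
    zero.  Non-convergence is reported through ``converged``, not raised.
    """
    x0 = np.asarray(sample.days if isinstance(sample, OnsetSample) else sample,
                    dtype=float)
    if x0.size < 10:
        raise ValueError("need at least 10 onset values to fit")
    if np.any(x0 <= 0):
        raise ValueError("onset values must be positive")

    loc = 0.0
    if three_parameter:
        upper = float(x0.min()) - 1e-6

        def neg_profile(g: float) -> float:
            k, lam, _ = _fit_two_parameter(x0 - g)
            return -_loglik(k, lam, x0 - g) if math.isfinite(k) else math.inf

        res = optimize.minimize_scalar(neg_profile, bounds=(0.0, max(upper, 0.0)),
                                       method="bounded",
                                       options={"xatol": 1e-6})
        loc = float(res.x) if res.success else 0.0

    x = x0 - loc
    k, lam, ok = _fit_two_parameter(x)
    if not math.isfinite(k):
        return WeibullFit(k, lam, loc, (math.nan, math.nan),
                          (math.nan, math.nan), math.inf, False, x0.size)
    ll = _loglik(k, lam, x)
    info = _hessian_log_scale(k, lam, x)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        shape_ci = (k * math.exp(-1.96 * se[0]), k * math.exp(1.96 * se[0]))
        scale_ci = (lam * math.exp(-1.96 * se[1]), lam * math.exp(1.96 * se[1]))
    except np.linalg.LinAlgError:
        shape_ci = scale_ci = (math.nan, math.nan)
        ok = False
    return WeibullFit(shape=k, scale=lam, location=loc, shape_ci=shape_ci,
                      scale_ci=scale_ci, loglik=ll, converged=ok, n=x0.size)


def hazard_label(fit: WeibullFit) -> str:
    """Classify the hazard trend from the shape estimate and its interval."""
    lo, hi = fit.shape_ci
    if fit.shape < 1 and hi < 1:
        return "decreasing hazard"
    if fit.shape > 1 and lo > 1:
        return "increasing hazard"
    return "indeterminate (interval includes constant hazard)"
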