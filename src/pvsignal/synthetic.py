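"""Synthetic FAERS-like data with known ground truth.

Spontaneous-report databases cannot be redistributed and carry no ground
truth, so every downstream stage here is exercised against generated
quarterly tables whose drug-event relative risks, demographic mix,
onset-time distribution, duplicate versions and deletion lists are all
chosen by configuration.  The generator works in the rare-event regime
(per-term report probabilities of a couple of percent at most) so that the
reporting odds ratio approximates the injected relative risk and
ground-truth recovery checks are meaningful.

Generated files round-trip through :mod:`pvsignal.faers_io` byte-for-byte;
the in-memory path (:func:`to_dataset`) applies the same typing code, so
file-based and in-memory pipelines agree.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import faers_io

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticFaers",
    "generate",
    "to_dataset",
    "write_files",
    "scenario_null",
    "scenario_reference_cohort",
    "simulate_regression_records",
]

TARGET_DRUG_NAME = "AVYCAZ (CEFTAZIDIME/AVIBACTAM)"
TARGET_SEARCH_NAMES = ("AVIBACTAM", "AVYCAZ", "EMBLAVEO", "ZAVICEFTA")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for one synthetic database.

    Defaults emulate a mid-sized spontaneous-report cohort for one suspect
    drug against a background of other suspect drugs: a few thousand cases,
    ~1-2 coded reactions per case, heavy age missingness, a male-skewed sex
    mix, Weibull early-onset latencies with shape < 1, plus duplicate report
    versions and quarterly deletion lists to exercise the cleaning chain.
    """

    n_cases: int = 9000
    target_drug_share: float = 0.1227
    n_background_drugs: int = 40
    n_pts: int = 150
    n_socs: int = 24
    base_pt_prob: float = 0.015
    signal_base_prob: float = 0.002
    #: (preferred term, relative risk under the target drug) pairs
    signal_specs: tuple[tuple[str, float], ...] = ()
    #: (drug name, probability given target exposure) pairs, role SS
    comedication_specs: tuple[tuple[str, float], ...] = ()
    #: (preferred term, comedication name, extra relative risk) triples
    interaction_specs: tuple[tuple[str, str, float], ...] = ()
    sex_probs: tuple[float, float, float] = (0.474, 0.269, 0.257)  # M, F, unk
    age_missing_prob: float = 0.634
    #: (low, high, probability) uniform mixture over age bands, in years
    age_bands: tuple[tuple[float, float, float], ...] = (
        (1, 18, 0.071), (18, 60, 0.415), (60, 80, 0.364), (80, 95, 0.150))
    country_probs: tuple[tuple[str, float], ...] = (
        ("CN", 0.259), ("US", 0.120), ("FR", 0.092), ("IT", 0.075),
        ("ES", 0.053), ("GB", 0.0802), ("DE", 0.0802), ("JP", 0.0802),
        ("BR", 0.0802), ("IN", 0.0802))
    occupation_probs: tuple[tuple[str, float], ...] = (
        ("MD", 0.497), ("HP", 0.182), ("CN", 0.153), ("PH", 0.132),
        ("OT", 0.029), ("", 0.007))
    year_probs: tuple[tuple[int, float], ...] = (
        (2015, 0.012), (2016, 0.023), (2017, 0.060), (2018, 0.069),
        (2019, 0.127), (2020, 0.108), (2021, 0.115), (2022, 0.111),
        (2023, 0.150), (2024, 0.174), (2025, 0.051))
    onset_shape: float = 0.7
    onset_scale: float = 8.0          # days
    start_date_missing_prob: float = 0.60
    event_date_missing_prob: float = 0.55
    duplicate_prob: float = 0.05
    deletion_prob: float = 0.02

    def validate(self) -> None:
        probs = [self.target_drug_share, self.base_pt_prob,
                 self.signal_base_prob, self.age_missing_prob,
                 self.start_date_missing_prob, self.event_date_missing_prob,
                 self.duplicate_prob, self.deletion_prob,
                 *self.sex_probs,
                 *(p for _, p in self.comedication_specs)]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if any(rr <= 0 for _, rr in self.signal_specs):
            raise ValueError("relative risks must be positive")
        if self.onset_shape <= 0 or self.onset_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if self.target_drug_share == 0 and self.signal_specs:
            raise ValueError("signal_specs require a nonzero target share")
        if self.n_pts < len(self.signal_specs):
            raise ValueError("n_pts smaller than the number of signal terms")


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery checks."""

    relative_risk: dict[str, float]            # PT -> RR under target drug
    interactions: list[tuple[str, str, float]]
    onset_shape: float
    onset_scale: float
    pt_soc: dict[str, str]
    n_target_cases: int                        # post-cleaning expectation basis
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticFaers:
    """Raw generated tables (string-valued, pre-cleaning) plus ground truth."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    deleted: list[str]
    pt_soc: pd.DataFrame
    ground_truth: GroundTruth


def _choice(rng, pairs, size):
    labels = np.array([k for k, _ in pairs], dtype=object)
    p = np.array([v for _, v in pairs], dtype=float)
    return rng.choice(labels, size=size, p=p / p.sum())


def _fmt_dates(ts: pd.Series, missing: np.ndarray) -> pd.Series:
    out = ts.dt.strftime("%Y%m%d").fillna("")
    out[missing] = ""
    return out


def generate(config: GeneratorConfig, seed: int) -> SyntheticFaers:
    """Draw one synthetic database.  Deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_cases

    caseid = np.arange(10_000_001, 10_000_001 + n).astype(str)
    target = rng.random(n) < config.target_drug_share

    # --- vocabulary and event probabilities -------------------------------
    signal_pts = [pt for pt, _ in config.signal_specs]
    n_bg = config.n_pts - len(signal_pts)
    pts = np.array(signal_pts + [f"SYNTHETIC EVENT {i:04d}" for i in range(n_bg)],
                   dtype=object)
    base = np.full(config.n_pts, config.base_pt_prob)
    base[: len(signal_pts)] = config.signal_base_prob
    rr = np.ones(config.n_pts)
    for i, (_, r) in enumerate(config.signal_specs):
        rr[i] = r
    pt_index = {pt: i for i, pt in enumerate(pts)}
    socs = [f"SYNTHETIC SOC {i:02d}" for i in range(config.n_socs)]
    pt_soc = {pt: socs[i % config.n_socs] for i, pt in enumerate(pts)}

    prob = np.tile(base, (n, 1))
    prob[target] *= rr

    comed_mask: dict[str, np.ndarray] = {}
    for name, p in config.comedication_specs:
        comed_mask[name] = target & (rng.random(n) < p)
    for pt, comed, extra in config.interaction_specs:
        if pt not in pt_index or comed not in comed_mask:
            raise ValueError(f"interaction references unknown pt/comedication: "
                             f"{pt!r}/{comed!r}")
        prob[comed_mask[comed], pt_index[pt]] *= extra

    occ = rng.random((n, config.n_pts)) < np.clip(prob, 0.0, 0.95)

    # --- demographics ------------------------------------------------------
    year = _choice(rng, config.year_probs, n).astype(int)
    day_of_year = rng.integers(0, 365, n)
    fda_dt = (pd.to_datetime(year.astype(str) + "0101", format="%Y%m%d")
              + pd.to_timedelta(day_of_year, unit="D"))
    sex = _choice(rng, list(zip(("M", "F", ""), config.sex_probs)), n)
    band = _choice(rng, [(i, p) for i, (_, _, p) in enumerate(config.age_bands)], n)
    lo = np.array([b[0] for b in config.age_bands])[band.astype(int)]
    hi = np.array([b[1] for b in config.age_bands])[band.astype(int)]
    age = np.round(lo + rng.random(n) * (hi - lo), 0)
    age_missing = rng.random(n) < config.age_missing_prob
    country = _choice(rng, config.country_probs, n)
    occp = _choice(rng, config.occupation_probs, n)

    # --- dates -------------------------------------------------------------
    delay = rng.integers(7, 120, n)
    start_dt = fda_dt - pd.to_timedelta(delay, unit="D")
    start_missing = rng.random(n) < config.start_date_missing_prob

    # --- versioned reports: duplicates get a second, higher version --------
    dup = rng.random(n) < config.duplicate_prob
    versions = [np.ones(n, dtype=int)]
    case_rows = [np.arange(n)]
    if dup.any():
        versions.append(np.full(int(dup.sum()), 2, dtype=int))
        case_rows.append(np.nonzero(dup)[0])
    row_case = np.concatenate(case_rows)
    row_version = np.concatenate(versions)
    row_pid = np.array([f"{caseid[i]}{v}" for i, v in zip(row_case, row_version)],
                       dtype=object)
    row_fda = fda_dt[row_case] + pd.to_timedelta((row_version - 1) * 30, unit="D")

    demo = pd.DataFrame({
        "primaryid": row_pid,
        "caseid": caseid[row_case],
        "caseversion": row_version.astype(str),
        "fda_dt": pd.Series(row_fda).dt.strftime("%Y%m%d"),
        "age": np.where(age_missing[row_case], "", age[row_case].astype(int).astype(str)),
        "age_cod": np.where(age_missing[row_case], "", "YR"),
        "sex": sex[row_case],
        "occp_cod": occp[row_case],
        "occr_country": country[row_case],
    })

    # --- drug rows ---------------------------------------------------------
    bg_drug = rng.integers(0, config.n_background_drugs, n)
    drug_frames = []
    name_ps = np.where(target, TARGET_DRUG_NAME,
                       np.array([f"SYNTHETIC DRUG {k:03d}" for k in bg_drug],
                                dtype=object))
    ps = pd.DataFrame({"primaryid": row_pid, "caseid": caseid[row_case],
                       "drug_seq": "1", "role_cod": "PS",
                       "drugname": name_ps[row_case]})
    drug_frames.append(ps)
    for seq_offset, (name, _) in enumerate(config.comedication_specs, start=2):
        mask = comed_mask[name][row_case]
        drug_frames.append(pd.DataFrame({
            "primaryid": row_pid[mask], "caseid": caseid[row_case][mask],
            "drug_seq": str(seq_offset), "role_cod": "SS", "drugname": name}))
    drug = pd.concat(drug_frames, ignore_index=True)

    # --- reactions with Weibull onsets ------------------------------------
    ev_case, ev_pt = np.nonzero(occ)
    onset = np.maximum(
        np.ceil(rng.weibull(config.onset_shape, ev_case.size) * config.onset_scale),
        1.0).astype(int)
    # latency k days maps to event date = start + (k - 1) so that the
    # downstream "+1 day, same-day = 1" convention recovers k exactly
    ev_date = start_dt[ev_case] + pd.to_timedelta(onset - 1, unit="D")
    ev_missing = (rng.random(ev_case.size) < config.event_date_missing_prob) \
        | start_missing[ev_case]
    reac_one = pd.DataFrame({
        "case_row": ev_case,
        "pt": pts[ev_pt],
        "event_dt": _fmt_dates(pd.Series(ev_date), ev_missing),
    })
    # replicate reaction rows for every report version of the case
    ver = pd.DataFrame({"case_row": row_case, "primaryid": row_pid,
                        "caseid": caseid[row_case]})
    reac = ver.merge(reac_one, on="case_row")[
        ["primaryid", "caseid", "pt", "event_dt"]]

    ther_one = pd.DataFrame({
        "case_row": np.arange(n),
        "dsg_drug_seq": "1",
        "start_dt": _fmt_dates(pd.Series(start_dt), start_missing),
    })
    ther = ver.merge(ther_one, on="case_row")[
        ["primaryid", "caseid", "dsg_drug_seq", "start_dt"]]

    deleted = sorted(caseid[rng.random(n) < config.deletion_prob])

    truth = GroundTruth(
        relative_risk={pt: float(r) for pt, r in zip(pts, rr)},
        interactions=[list(t) for t in config.interaction_specs],
        onset_shape=config.onset_shape,
        onset_scale=config.onset_scale,
        pt_soc=pt_soc,
        n_target_cases=int(target.sum()) - int((target & np.isin(caseid, deleted)).sum()),
        seed=seed,
    )
    pt_soc_frame = pd.DataFrame({"pt": list(pt_soc), "soc": list(pt_soc.values())})
    return SyntheticFaers(demo, drug, reac, ther, list(deleted),
                          pt_soc_frame, truth)


def to_dataset(synth: SyntheticFaers) -> tuple[faers_io.Dataset, set[str]]:
    """Type the raw tables in memory (same code path as file reading) and
    return the pre-cleaning dataset plus its deletion set."""
    ds = faers_io.Dataset(
        faers_io.type_table(synth.demo, "demo"),
        faers_io.type_table(synth.drug, "drug"),
        faers_io.type_table(synth.reac, "reac"),
        faers_io.type_table(synth.ther, "ther"),
    )
    return ds, set(synth.deleted)


def _quarter_of(fda_dt: pd.Series) -> pd.Series:
    d = pd.to_datetime(fda_dt, format="%Y%m%d", errors="coerce")
    return d.dt.year.astype(str) + "q" + d.dt.quarter.astype(str)


def write_files(synth: SyntheticFaers, out_dir: str | Path) -> list[Path]:
    """Emit quarterly ``$``-delimited files plus the deletion lists, the
    PT-to-SOC map and ``ground_truth.json``.  Returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    quarter = _quarter_of(synth.demo["fda_dt"])
    pid_quarter = dict(zip(synth.demo["primaryid"], quarter))

    def _write(df: pd.DataFrame, kind: str, q: str) -> None:
        path = out_dir / f"{kind}_{q}.txt"
        path.write_text("$".join(df.columns) + "\n"
                        + "\n".join("$".join(map(str, row))
                                    for row in df.itertuples(index=False))
                        + ("\n" if len(df) else ""))
        written.append(path)

    for kind, df in (("demo", synth.demo), ("drug", synth.drug),
                     ("reac", synth.reac), ("ther", synth.ther)):
        q = df["primaryid"].map(pid_quarter)
        for qname, part in sorted(df.groupby(q, sort=True)):
            _write(part, kind, qname)

    case_quarter = dict(zip(synth.demo["caseid"], quarter))
    dele = pd.DataFrame({"caseid": synth.deleted})
    if len(dele):
        for qname, part in sorted(dele.groupby(dele["caseid"].map(case_quarter))):
            _write(part, "deleted", qname)

    map_path = out_dir / "pt_soc_map.tsv"
    synth.pt_soc.to_csv(map_path, sep="\t", index=False)
    written.append(map_path)
    gt_path = out_dir / "ground_truth.json"
    gt_path.write_text(synth.ground_truth.to_json())
    written.append(gt_path)
    return written


# ---------------------------------------------------------------------------
# canned scenarios

def scenario_null(seed: int, n_cases: int = 20000,
                  n_pts: int = 200) -> SyntheticFaers:
    """No injected signals: every drug-event relative risk is 1.  Used for
    type-I-error calibration of the screening thresholds."""
    cfg = GeneratorConfig(
        n_cases=n_cases, n_pts=n_pts, target_drug_share=0.25,
        base_pt_prob=0.005, signal_specs=(), comedication_specs=(),
        duplicate_prob=0.03, deletion_prob=0.01)
    return generate(cfg, seed)


REFERENCE_SIGNALS = (
    ("PATHOGEN RESISTANCE", 50.0),
    ("SEPTIC SHOCK", 15.0),
    ("DRUG-INDUCED LIVER INJURY", 12.0),
    ("PLATELET COUNT DECREASED", 7.0),
    ("RESPIRATORY FAILURE", 6.0),
    ("ACUTE KIDNEY INJURY", 5.0),
    ("DEATH", 5.0),
)

REFERENCE_COMEDICATIONS = (
    ("MEROPENEM", 0.25),
    ("VANCOMYCIN", 0.15),
    ("TIGECYCLINE", 0.10),
    ("AMIKACIN", 0.05),
)

REFERENCE_INTERACTIONS = (
    ("RESPIRATORY FAILURE", "MEROPENEM", 3.0),
    ("ACUTE KIDNEY INJURY", "VANCOMYCIN", 2.0),
)


def scenario_reference_cohort(seed: int) -> SyntheticFaers:
    """A cohort echoing the shape of a real single-drug safety study:
    roughly a thousand target-drug cases, ~2.3 coded reactions per case,
    ~63% missing age, a male-skewed sex mix, one very strong injected
    signal (relative risk 50) plus several moderate ones, comedications
    with outcome interactions, and early-onset Weibull latencies."""
    cfg = GeneratorConfig(
        signal_specs=REFERENCE_SIGNALS,
        comedication_specs=REFERENCE_COMEDICATIONS,
        interaction_specs=REFERENCE_INTERACTIONS,
    )
    return generate(cfg, seed)


# ---------------------------------------------------------------------------
# direct covariate simulation for the regression module

def simulate_regression_records(n: int, seed: int,
                                or_exposure: float = 3.0) -> tuple[pd.DataFrame, dict]:
    """Case-level records with a confounded binary exposure.

    Age and nephrotoxin use drive both the exposure and the outcome, so the
    crude odds ratio is biased away from *or_exposure* and only the adjusted
    model recovers it.  Returns (records, true coefficient dict).
    """
    rng = np.random.default_rng(seed)
    age = np.clip(rng.normal(55, 15, n), 18, 95)
    neph = rng.random(n) < 0.25
    sex = np.where(rng.random(n) < 0.6, "male", "female")
    year = rng.integers(2015, 2026, n)
    lin_x = -1.2 + 0.08 * (age - 55) + 1.2 * neph
    exposure = rng.random(n) < 1 / (1 + np.exp(-lin_x))
    truth = {"intercept": -2.2, "exposure": float(np.log(or_exposure)),
             "age_per10": 0.60, "nephrotoxin": 0.80, "male": 0.20,
             "year": 0.0}
    lin_y = (truth["intercept"] + truth["exposure"] * exposure
             + truth["age_per10"] * (age - 55) / 10.0
             + truth["nephrotoxin"] * neph
             + truth["male"] * (sex == "male"))
    outcome = rng.random(n) < 1 / (1 + np.exp(-lin_y))
    records = pd.DataFrame({
        "outcome": outcome.astype(int), "exposure": exposure.astype(int),
        "age_years": age, "sex": sex, "report_year": year,
        "nephrotoxin": neph.astype(int)})
    return records, truth
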