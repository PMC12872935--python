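"""Subgroup, period and regimen comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pvsignal.contingency import TargetDrug
from pvsignal.stratified import (age_strata, compare_periods, compare_regimens,
                                 compare_strata, sex_strata)


def _flat(rows, year=None):
    """rows: (caseid, pt); optionally a caseid->year map for periods."""
    df = pd.DataFrame(rows, columns=["caseid", "pt"])
    df["normalized_name"] = "AVYCAZ"
    df["role"] = "PS"
    if year is not None:
        df["report_year"] = df["caseid"].map(year)
    return df


def _strata(mapping):
    return pd.Series(mapping, dtype=object)


def test_identical_distribution_is_null():
    rows = [(f"a{i}", "X") for i in range(20)] + [(f"a{i}", "Y") for i in range(20)]
    rows += [(f"b{i}", "X") for i in range(20)] + [(f"b{i}", "Y") for i in range(20)]
    lab = _strata({f"a{i}": "A" for i in range(20)} | {f"b{i}": "B" for i in range(20)})
    out = compare_strata(_flat(rows), lab).set_index("term")
    assert out.loc["x", "effect_log2"] == pytest.approx(0.0)
    assert out.loc["x", "p_value"] == pytest.approx(1.0, abs=1e-9)
    assert not out["significant"].any()


def test_swapping_strata_negates_effect():
    rows = ([(f"a{i}", "X") for i in range(12)] + [(f"a{i}", "Y") for i in range(30)]
            + [(f"b{i}", "X") for i in range(3)] + [(f"b{i}", "Y") for i in range(30)])
    lab = _strata({f"a{i}": "A" for i in range(30)} | {f"b{i}": "B" for i in range(30)})
    swapped = lab.map({"A": "B", "B": "A"})
    out = compare_strata(_flat(rows), lab).set_index("term")
    out2 = compare_strata(_flat(rows), swapped).set_index("term")
    assert out2.loc["x", "effect_log2"] == pytest.approx(-out.loc["x", "effect_log2"])
    assert out2.loc["x", "p_value"] == pytest.approx(out.loc["x", "p_value"], rel=1e-9)


def test_zero_cell_continuity_correction_gives_finite_positive_effect():
    # term only ever seen in stratum A
    rows = ([(f"a{i}", "ONLY A") for i in range(5)]
            + [(f"a{i}", "COMMON") for i in range(20)]
            + [(f"b{i}", "COMMON") for i in range(25)])
    lab = _strata({f"a{i}": "A" for i in range(20)} | {f"b{i}": "B" for i in range(25)})
    out = compare_strata(_flat(rows), lab).set_index("term")
    eff = out.loc["only a", "effect_log2"]
    # hand value with +0.5 on each cell: log2(5.5*25.5 / (20.5*0.5))
    assert eff == pytest.approx(np.log2(5.5 * 25.5 / (20.5 * 0.5)))
    assert np.isfinite(eff) and eff > 0


def test_min_count_filter_and_degenerate_stratifier():
    rows = [("a1", "RARE"), ("a1", "X"), ("b1", "X"), ("a2", "X"), ("b2", "X")]
    lab = _strata({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    out = compare_strata(_flat(rows), lab, min_count=3)
    assert "rare" not in set(out["term"])
    with pytest.raises(ValueError, match="degenerate"):
        compare_strata(_flat(rows), _strata({"a1": "A", "a2": "A"}))


def test_compare_periods_split_and_conservation():
    year = {f"c{i}": (2017 if i < 30 else 2023) for i in range(60)}
    rows = [(f"c{i}", "X") for i in range(60)]
    rows += [(f"c{i}", "LATE PT") for i in range(25, 60)]   # late-enriched
    flat = _flat(rows, year)
    out = compare_periods(flat, cutoff_year=2020).set_index("term")
    assert out.loc["x", "n_in_A"] + out.loc["x", "n_in_B"] == 60
    # late-period enrichment: relatively more frequent in B -> negative A-vs-B
    assert out.loc["late pt", "effect_log2"] < 0
    assert out.loc["late pt", "p_value"] < 0.05
    with pytest.raises(ValueError):
        compare_periods(flat, cutoff_year=1990)


def test_age_and_sex_strata_builders():
    cases = pd.DataFrame({
        "caseid": ["1", "2", "3", "4", "5"],
        "age_years": [30.0, 70.0, np.nan, 17.0, 64.9],
        "sex": ["male", "female", "unknown", "male", "female"],
    })
    a = age_strata(cases)
    assert a["1"] == "A" and a["2"] == "B" and a["3"] == "" and a["4"] == ""
    assert a["5"] == "A"        # left-closed, right-open band
    s = sex_strata(cases)
    assert s["1"] == "A" and s["2"] == "B" and s["3"] == ""


def test_compare_regimens_interaction_detected_and_warning_path():
    rng = np.random.default_rng(21)
    rows, drug = [], {}
    soc_map = {"RESP FAILURE": "RESPIRATORY SOC", "OTHER PT": "OTHER SOC"}
    for i in range(400):
        cid = f"c{i}"
        combo = i < 200
        drug[cid] = combo
        if rng.random() < (0.30 if combo else 0.08):
            rows.append((cid, "RESP FAILURE"))
        if rng.random() < 0.5:
            rows.append((cid, "OTHER PT"))
        rows.append((cid, "FILLER"))
    flat = pd.DataFrame(rows, columns=["caseid", "pt"])
    flat["normalized_name"] = np.where(flat["caseid"].map(drug), "MEROPENEM", "AVYCAZ")
    flat["role"] = "SS"
    # every case also has the target drug as PS
    tgt = flat.drop_duplicates("caseid").assign(normalized_name="AVYCAZ", role="PS")
    flat = pd.concat([flat, tgt], ignore_index=True)
    target = TargetDrug(("AVYCAZ",))
    out = compare_regimens(flat, "MEROPENEM", target, soc_map)
    resp = out.set_index("term").loc["RESPIRATORY SOC"]
    assert resp["or_"] > 1 and resp["or_lo"] > 1 and resp["significant"]
    # order invariance
    out2 = compare_regimens(flat.sample(frac=1, random_state=3), "MEROPENEM",
                            target, soc_map)
    pd.testing.assert_frame_equal(out, out2)
    with pytest.warns(UserWarning, match="absent"):
        empty = compare_regimens(flat, "NOSUCHDRUG", target, soc_map)
    assert empty.empty


def test_type_one_error_calibration_under_independence():
    # stratum-independent generation over 300 terms: the significant
    # fraction should sit near the nominal 5% level
    rng = np.random.default_rng(42)
    rows = []
    lab = {}
    for i in range(3000):
        cid = f"c{i}"
        lab[cid] = "A" if rng.random() < 0.5 else "B"
        for t in np.nonzero(rng.random(300) < 0.01)[0]:
            rows.append((cid, f"T{t:03d}"))
        rows.append((cid, "ANCHOR"))
    out = compare_strata(_flat(rows), _strata(lab), min_count=3)
    out = out[out["term"] != "anchor"]
    frac = out["significant"].mean()
    assert 0.02 <= frac <= 0.09


def test_chi2_and_fisher_branches_agree_on_large_counts():
    rng = np.random.default_rng(8)
    agree = 0
    n = 200
    for _ in range(n):
        a, b, c, d = rng.integers(20, 400, 4)
        p_chi = stats.chi2_contingency([[a, b], [c, d]], correction=False)[1]
        p_f = stats.fisher_exact([[a, b], [c, d]])[1]
        agree += (p_chi < 0.05) == (p_f < 0.05)
    assert agree / n >= 0.95
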