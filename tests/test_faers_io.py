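"""Parsing, quarter consolidation, deletion purge, dedup and joins."""

import warnings

import numpy as np
import pandas as pd
import pytest

from pvsignal import faers_io
from pvsignal.faers_io import (SchemaError, consolidate_deletions,
                               deduplicate_cases, clean_dataset,
                               filter_target_drug, join_case_level,
                               merge_quarters, read_ascii_table,
                               remove_deleted_cases, validate_counts)


def test_read_demo_rows_and_missing_values(tmp_path):
    f = tmp_path / "demo_2020q1.txt"
    f.write_text("primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$occp_cod$occr_country\n"
                 "101$10$1$20200315$55$YR$M$MD$US\n"
                 "201$20$1$202004$XX$YR$F$CN$\n")
    t = read_ascii_table(f, "demo")
    assert len(t) == 2                       # rows = lines minus header
    assert t.loc[0, "age_years"] == 55 and t.loc[0, "sex"] == "male"
    assert pd.isna(t.loc[1, "age_years"])    # unparseable age -> missing
    # partial date padded to first of month
    assert t.loc[1, "receipt_date"] == pd.Timestamp("2020-04-01")
    assert t.loc[1, "report_year"] == 2020
    assert pd.isna(t.loc[1, "country"])
    assert t.loc[1, "reporter_occupation"] == "consumer"


@pytest.mark.parametrize("code,age,expected", [
    ("YR", "50", 50.0), ("DEC", "5", 50.0), ("MON", "6", 0.5),
    ("", "40", 40.0), ("QQ", "40", None), ("YR", "300", None),
])
def test_age_code_conversion(tmp_path, code, age, expected):
    f = tmp_path / "demo_x.txt"
    f.write_text("primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$occp_cod$occr_country\n"
                 f"1$1$1$20200101${age}${code}$M$MD$US\n")
    got = read_ascii_table(f, "demo").loc[0, "age_years"]
    assert (pd.isna(got) if expected is None else got == expected)


def test_read_drug_role_codes(tmp_path):
    f = tmp_path / "drug_2020q1.txt"
    f.write_text("primaryid$caseid$drug_seq$role_cod$drugname\n"
                 "101$10$1$C$meropenem \n")
    t = read_ascii_table(f, "drug")
    assert t.loc[0, "role"] == "C"
    assert t.loc[0, "normalized_name"] == "MEROPENEM"


def test_missing_header_column_names_the_column(tmp_path):
    f = tmp_path / "demo_bad.txt"
    f.write_text("primaryid$caseid$caseversion$fda_dt$age$age_cod$occp_cod$occr_country\n")
    with pytest.raises(SchemaError, match="sex"):
        read_ascii_table(f, "demo")


def test_empty_file_warns_and_returns_empty(tmp_path):
    f = tmp_path / "reac_empty.txt"
    f.write_text("")
    with pytest.warns(UserWarning, match="empty"):
        t = read_ascii_table(f, "reac")
    assert len(t) == 0 and "pt" in t.columns


def test_merge_quarters_additivity_and_neutral_element(rows, dataset_builder):
    a = dataset_builder([rows.demo(str(i), str(i)) for i in range(10)], [], []).cases
    b = dataset_builder([rows.demo(str(i + 100), str(i + 100)) for i in range(15)],
                        [], []).cases
    empty = a.iloc[:0]
    assert len(merge_quarters([a, b])) == 25
    pd.testing.assert_frame_equal(merge_quarters([a, empty]), a)


def test_merge_quarters_schema_mismatch():
    with pytest.raises(SchemaError, match="extra"):
        merge_quarters([pd.DataFrame({"x": [1]}),
                        pd.DataFrame({"x": [1], "extra": [2]})])


def test_deletion_lists_union():
    assert consolidate_deletions([{"1", "2"}, {"2", "3"}, {"3"}]) == {"1", "2", "3"}
    frames = [pd.DataFrame({"caseid": ["1", "2"]}), pd.DataFrame({"caseid": ["2"]})]
    assert consolidate_deletions(frames) == {"1", "2"}


def _five_case_ds(rows, dataset_builder):
    demo = [rows.demo(str(100 + i), str(i)) for i in range(5)]
    drug = [rows.drug(str(100 + i), str(i)) for i in range(5)]
    reac = [rows.reac(str(100 + i), str(i), f"PT {i}") for i in range(5)]
    return dataset_builder(demo, drug, reac)


def test_remove_deleted_counts_and_referential_purge(rows, dataset_builder):
    ds = _five_case_ds(rows, dataset_builder)
    out = remove_deleted_cases(ds, {"1", "3"})
    assert len(out.cases) == 3
    # referential purge, checked by brute-force scan over child rows
    surviving = set(out.cases["primaryid"])
    for child in (out.drugs, out.events, out.therapies):
        assert all(pid in surviving for pid in child["primaryid"])
    assert not any(out.events["caseid"].isin({"1", "3"}))
    # ids absent from the dataset are a no-op
    untouched = remove_deleted_cases(ds, {"999"})
    pd.testing.assert_frame_equal(untouched.cases, ds.cases)


def test_dedup_keeps_highest_version_then_latest_receipt(rows, dataset_builder):
    demo = [rows.demo("101", "1", ver=1), rows.demo("102", "1", ver=2),
            rows.demo("201", "2", ver=1, fda="20230101"),
            rows.demo("202", "2", ver=1, fda="20240101")]
    ds = dataset_builder(demo, [], [])
    out = deduplicate_cases(ds)
    kept = dict(zip(out.cases["caseid"], out.cases["primaryid"]))
    assert kept == {"1": "102", "2": "202"}
    # idempotence
    pd.testing.assert_frame_equal(deduplicate_cases(out).cases, out.cases)


def test_cleaning_chain_idempotent_and_order_independent(rows, dataset_builder):
    rng = np.random.default_rng(11)
    demo, drug, reac = [], [], []
    for i in range(30):
        for v in range(1, int(rng.integers(2, 4))):
            pid = f"{i}{v}"
            demo.append(rows.demo(pid, str(i), ver=v,
                                  fda=f"202{rng.integers(0, 5)}0{rng.integers(1, 10)}15"))
            drug.append(rows.drug(pid, str(i)))
            reac.append(rows.reac(pid, str(i), f"PT {rng.integers(0, 5)}"))
    ds = dataset_builder(demo, drug, reac)
    deleted = {"3", "7"}

    once = clean_dataset(ds, deleted)
    twice = clean_dataset(once, deleted)
    pd.testing.assert_frame_equal(once.cases, twice.cases)
    pd.testing.assert_frame_equal(once.events, twice.events)
    # one record per caseid, count = distinct surviving case ids
    assert once.cases["caseid"].is_unique
    assert len(once.cases) == ds.cases["caseid"].nunique() - len(deleted)

    # shuffling input rows leaves the cleaned content unchanged
    shuffled = faers_io.Dataset(
        ds.cases.sample(frac=1, random_state=5).reset_index(drop=True),
        ds.drugs.sample(frac=1, random_state=6).reset_index(drop=True),
        ds.events.sample(frac=1, random_state=7).reset_index(drop=True),
        ds.therapies)
    other = clean_dataset(shuffled, deleted)
    key = ["primaryid", "caseid"]
    pd.testing.assert_frame_equal(
        once.cases.sort_values(key).reset_index(drop=True),
        other.cases.sort_values(key).reset_index(drop=True))
    pd.testing.assert_frame_equal(
        once.events.sort_values(key + ["pt"]).reset_index(drop=True),
        other.events.sort_values(key + ["pt"]).reset_index(drop=True))


def test_join_case_level_semantics(rows, dataset_builder):
    demo = [rows.demo("101", "1"), rows.demo("201", "2"), rows.demo("301", "3")]
    drug = [rows.drug("101", "1", seq=1), rows.drug("101", "1", seq=2, name="MEROPENEM"),
            rows.drug("201", "2")]
    reac = [rows.reac("101", "1", "PT A"), rows.reac("101", "1", "PT B"),
            rows.reac("101", "1", "PT C"),
            rows.reac("301", "3", "PT D")]     # case 3 has events but no drugs
    flat = join_case_level(dataset_builder(demo, drug, reac))
    assert (flat["caseid"] == "1").sum() == 6          # 2 drugs x 3 PTs
    # case with drugs but no events survives with an empty event set
    case2 = flat[flat["caseid"] == "2"]
    assert len(case2) == 1 and pd.isna(case2["pt"]).all()
    # case with events but no drugs is dropped by the inner join
    assert "3" not in set(flat["caseid"])


def test_filter_target_drug(rows, dataset_builder):
    demo = [rows.demo("101", "1"), rows.demo("201", "2"), rows.demo("301", "3")]
    drug = [rows.drug("101", "1", name="AVYCAZ (ceftazidime/avibactam)", role="PS"),
            rows.drug("201", "2", name="avibactam", role="C"),
            rows.drug("301", "3", name="MEROPENEM", role="PS")]
    ds = dataset_builder(demo, drug, [])
    out = filter_target_drug(ds, ["Avibactam", "Avycaz"], role="PS")
    assert set(out.cases["caseid"]) == {"1"}           # C-role match excluded
    assert len(filter_target_drug(ds, ["ZAVICEFTA"]).cases) == 0
    with pytest.raises(ValueError):
        filter_target_drug(ds, [])


def test_validate_counts(rows, dataset_builder):
    ds = _five_case_ds(rows, dataset_builder)
    assert validate_counts(ds, 5)["ok"]
    bad = validate_counts(ds, 7)
    assert not bad["ok"] and bad["tables"]["cases"]["delta"] == -2
    info = validate_counts(ds)
    assert info["informational"] and info["ok"]
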