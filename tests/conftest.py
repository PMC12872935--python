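import pandas as pd
import pytest

from pvsignal import faers_io


def _frame(rows, columns):
    return pd.DataFrame(list(rows), columns=columns).astype(str)


def build_dataset(demo, drug, reac, ther=()):
    """Build a typed Dataset from tuples in schema column order.

    reac rows may carry 3 fields (no event date) or 4 (with event_dt);
    goes through the same typing path as file reading.
    """
    reac = list(reac)
    reac_cols = faers_io.SCHEMAS["reac"] + (
        ["event_dt"] if reac and len(reac[0]) == 4 else [])
    return faers_io.Dataset(
        faers_io.type_table(_frame(demo, faers_io.SCHEMAS["demo"]), "demo"),
        faers_io.type_table(_frame(drug, faers_io.SCHEMAS["drug"]), "drug"),
        faers_io.type_table(_frame(reac, reac_cols), "reac"),
        faers_io.type_table(_frame(ther, faers_io.SCHEMAS["ther"]), "ther"),
    )


def demo_row(pid, caseid, ver=1, fda="20200115", age="50", age_cod="YR",
             sex="M", occp="MD", country="US"):
    return (pid, caseid, str(ver), fda, age, age_cod, sex, occp, country)


def drug_row(pid, caseid, seq=1, role="PS", name="AVYCAZ (CEFTAZIDIME/AVIBACTAM)"):
    return (pid, caseid, str(seq), role, name)


def reac_row(pid, caseid, pt, event_dt=None):
    return (pid, caseid, pt) if event_dt is None else (pid, caseid, pt, event_dt)


def ther_row(pid, caseid, seq=1, start="20200101"):
    return (pid, caseid, str(seq), start)


@pytest.fixture
def dataset_builder():
    return build_dataset


@pytest.fixture
def rows():
    class Rows:
        demo = staticmethod(demo_row)
        drug = staticmethod(drug_row)
        reac = staticmethod(reac_row)
        ther = staticmethod(ther_row)
    return Rows
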