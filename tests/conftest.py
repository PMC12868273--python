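import numpy as np
import pandas as pd
import pytest

from pvfaers.dictionaries import DictionaryMaps
from pvfaers.io_faers import FaersDialect


@pytest.fixture(scope="session")
def maps() -> DictionaryMaps:
    return DictionaryMaps.bundled()


@pytest.fixture
def dialect() -> FaersDialect:
    return FaersDialect()


@pytest.fixture
def demo_frame() -> pd.DataFrame:
    """Small DEMO table with a duplicated case and an FDA_DT tie."""
    return pd.DataFrame(
        {
            "primaryid": ["1001", "1002", "2001", "3001", "3002"],
            "caseid": ["100", "100", "200", "300", "300"],
            "fda_dt": ["20230101", "20230301", "20230215", "20230110", "20230110"],
            "event_dt": ["20221231", "20221231", "20230201", "", ""],
            "age": ["47", "47", "6", "", ""],
            "age_cod": ["YR", "YR", "MON", "", ""],
            "sex": ["F", "F", "M", "", ""],
            "occp_cod": ["MD", "MD", "CN", "LW", "LW"],
            "reporter_country": ["US", "US", "CA", "GB", "GB"],
            "occr_country": ["US", "US", "CA", "GB", "GB"],
        }
    )


@pytest.fixture
def quarter_dir(tmp_path, demo_frame):
    """A tiny on-disk FAERS quarter with a deletion list."""
    from pvfaers.io_faers import write_faers_table

    qdir = tmp_path / "2019Q1"
    qdir.mkdir()
    write_faers_table(demo_frame, qdir / "DEMO2019Q1.txt")
    drug = pd.DataFrame(
        {
            "primaryid": ["1002", "2001", "3001"],
            "caseid": ["100", "200", "300"],
            "drug_seq": ["1", "1", "1"],
            "role_cod": ["PS", "PS", "PS"],
            "drugname": ["DUPIXENT", "RESTASIS", "unknownium"],
        }
    )
    write_faers_table(drug, qdir / "DRUG2019Q1.txt")
    reac = pd.DataFrame(
        {
            "primaryid": ["1002", "1002", "2001", "3001"],
            "caseid": ["100", "100", "200", "300"],
            "pt": ["Vision blurred", "Nausea", "Dry eye", "Headache"],
        }
    )
    write_faers_table(reac, qdir / "REAC2019Q1.txt")
    ther = pd.DataFrame(
        {
            "primaryid": ["1002", "2001"],
            "caseid": ["100", "200"],
            "dsg_drug_seq": ["1", "1"],
            "start_dt": ["20221201", "20230110"],
            "end_dt": ["", ""],
        }
    )
    write_faers_table(ther, qdir / "THER2019Q1.txt")
    outc = pd.DataFrame(
        {"primaryid": ["1002", "1002"], "caseid": ["100", "100"],
         "outc_cod": ["HO", "DS"]}
    )
    write_faers_table(outc, qdir / "OUTC2019Q1.txt")
    (qdir / "DELETED2019Q1.txt").write_text("300\n999\n", encoding="utf-8")
    return qdir


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
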