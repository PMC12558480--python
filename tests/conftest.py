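import pandas as pd
import pytest

from pvsignal.io import ReportBundle


def _demo(rows):
    cols = ["report_id", "case_id", "receipt_date", "event_date", "sex",
            "age_value", "age_unit", "reporter", "country"]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def toy_bundle() -> ReportBundle:
    """Three-case hand-built bundle: one duplicated case, one target report
    with repeated PTs, one secondary-suspect-only report."""
    demo = _demo([
        # case C1 has two versions; r2 is more recent and must be kept
        ("r1", "C1", "20200101", "20191220", "F", 54.0, "YR", "physician", "US"),
        ("r2", "C1", "20210101", "20191220", "F", 54.0, "YR", "physician", "US"),
        ("r3", "C2", "20200301", "20200215", "M", 5.0, "DEC", "consumer", "JP"),
        ("r4", "C3", "20200401", "", "UNK", None, "UNK", "pharmacist", "US"),
    ])
    drug = pd.DataFrame({
        "report_id": ["r1", "r2", "r3", "r4", "r4"],
        "drug_seq": [1, 1, 1, 1, 2],
        "role": ["PS", "PS", "SS", "PS", "C"],
        "drugname": ["CINACALCET", "SENSIPAR 30MG TABLET", "cinacalcet hcl",
                     "CALCITRIOL", "SENSIPAR"],
        "active_ingredient": [None, None, None, None, "CINACALCET HYDROCHLORIDE"],
    })
    reac = pd.DataFrame({
        "report_id": ["r2", "r2", "r2", "r3", "r3", "r4"],
        "pt": ["Nausea", "nausea", "Vomiting", "Hypocalcaemia", "Nausea", "Tetany"],
    })
    ther = pd.DataFrame({
        "report_id": ["r2", "r3"],
        "drug_seq": [1, 1],
        "start_date": ["20191201", "20200201"],
        "end_date": ["20200301", ""],
    })
    outc = pd.DataFrame({
        "report_id": ["r2", "r2", "r3"],
        "outcome": ["HO", "DE", "HO"],
    })
    return ReportBundle(demo=demo, drug=drug, reac=reac, ther=ther, outc=outc)
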