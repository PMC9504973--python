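import pandas as pd
import pytest

from pvsignal.srs_io import Database


@pytest.fixture
def tiny_db() -> Database:
    """Hand-built four-table database exercising linkage, involvement,
    duplicate PTs, partial dates and an orphan row.

    Expected suspect-only pairs: (A, drugX, pt1) with worst outcome death
    and two start dates; (A, drugX, pt2); (B, drugX, pt1) with a
    month-precision start; (C, drugY, pt2).
    """
    demo = pd.DataFrame(
        {
            "case_id": ["A", "B", "C"],
            "sex": ["female", "female", "male"],
            "age_band": ["50-59", "60-69", "70-79"],
            "report_period": ["2020-Q2", "2020-Q1", "2019-Q3"],
        }
    )
    drug = pd.DataFrame(
        {
            "case_id": ["A", "A", "A", "B", "C"],
            "drug_name": ["drugX", "drugX", "drugY", "drugX", "drugY"],
            "involvement": ["suspect", "suspect", "concomitant", "suspect", "suspect"],
            "start_date": ["2020-01-01", "2020-03-01", "2020-01-05", "2020-02", "2019-06-01"],
            "end_date": ["2020-02-01", "2020-04-01", "", "", ""],
            "route": ["oral"] * 5,
        }
    )
    reac = pd.DataFrame(
        {
            "case_id": ["A", "A", "A", "B", "C", "Z"],
            "pt": ["pt1", "pt1", "pt2", "pt1", "pt2", "pt1"],
            "onset_date": ["2020-03-05", "2020-03-07", "2020-01-01", "2020-02", "2019-06-01", "2020-05-05"],
            "outcome": ["recovered", "death", "missing", "remission", "unclear", "death"],
        }
    )
    hist = pd.DataFrame(
        {"case_id": ["A", "B"], "disease": ["ovarian cancer", "breast cancer"]}
    )
    return Database(
        demo=demo.astype(str), drug=drug.astype(str),
        reac=reac.astype(str), hist=hist.astype(str),
    )


@pytest.fixture(scope="session")
def small_synth():
    """A mid-size default-condition synthetic database with its ledger.

    12,000 cases keeps the planted (olaparib, anaemia) pair comfortably
    above the 10-case signal screen (expected a is about 23) while staying
    fast to generate.
    """
    from pvsignal.synthetic import default_config, generate

    return generate(default_config(n_cases=12_000, seed=11))
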