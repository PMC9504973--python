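"""Table reading/writing, partial dates and case linkage."""

import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.srs_io import (
    CsvDialect,
    PartialDate,
    SchemaError,
    iso_precision,
    link_cases,
    read_tables,
    write_tables,
)
from pvsignal.synthetic import default_config, generate


@pytest.mark.parametrize(
    "text, precision, iso",
    [
        ("20200110", "day", "2020-01-10"),
        ("2020-01-10", "day", "2020-01-10"),
        ("2020/01/10", "day", "2020-01-10"),
        ("202001", "month", "2020-01"),
        ("2020-01", "month", "2020-01"),
        ("2020", "year", "2020"),
        ("", "missing", ""),
        ("nan", "missing", ""),
        ("20200230", "month", "2020-02"),  # invalid day degrades
        ("20201510", "year", "2020"),  # invalid month degrades
        ("0202", "missing", ""),  # implausible year
        ("notadate", "missing", ""),
    ],
)
def test_partial_date_parse_and_degrade(text, precision, iso):
    d = PartialDate.parse(text)
    assert d.precision == precision
    assert d.isoformat() == iso
    assert iso_precision(iso) == precision


@settings(derandomize=True, max_examples=150)
@given(st.dates(min_value=dt.date(1990, 1, 1), max_value=dt.date(2030, 12, 31)))
def test_partial_date_day_roundtrip_and_ordering(date):
    d = PartialDate.parse(date.strftime("%Y%m%d"))
    assert d.precision == "day"
    assert d.to_date() == date
    # compact and iso forms re-parse identically
    assert PartialDate.parse(d.compact()) == d
    assert PartialDate.parse(d.isoformat()) == d
    # sort keys agree with calendar arithmetic
    later = PartialDate.parse((date + dt.timedelta(days=1)).strftime("%Y%m%d"))
    assert d.sort_key() < later.sort_key()


def _write_db(db, tmp_path, dialect=None):
    paths = {t: tmp_path / f"{t}.csv" for t in ("demo", "drug", "reac", "hist")}
    write_tables(db, paths, dialect)
    return paths


def test_empty_files_give_empty_collections(tmp_path):
    from pvsignal.srs_io import Database

    paths = _write_db(Database.empty(), tmp_path)
    db = read_tables(paths)
    assert db.row_counts() == {"demo": 0, "drug": 0, "reac": 0, "hist": 0}


def test_missing_file_names_table(tmp_path, tiny_db):
    paths = _write_db(tiny_db, tmp_path)
    paths["reac"] = tmp_path / "nope.csv"
    with pytest.raises(FileNotFoundError, match="reac"):
        read_tables(paths)


def test_missing_mandatory_column_names_column(tmp_path, tiny_db):
    paths = _write_db(tiny_db, tmp_path)
    df = pd.read_csv(paths["drug"]).drop(columns=["drug_name"])
    df.to_csv(paths["drug"], index=False)
    with pytest.raises(SchemaError, match="drug_name"):
        read_tables(paths)


def test_month_precision_onset_survives_read(tmp_path, tiny_db):
    paths = _write_db(tiny_db, tmp_path)
    db = read_tables(paths)
    onset = db.reac.loc[
        (db.reac.case_id == "B") & (db.reac.pt == "pt1"), "onset_date"
    ].item()
    assert iso_precision(onset) == "month"


def test_dialect_maps_codes_and_columns(tmp_path):
    # JADER-like numeric involvement codes and renamed columns
    dialect = CsvDialect(
        columns={
            "demo": {"id": "case_id", "gender": "sex"},
            "drug": {"id": "case_id", "generic": "drug_name", "inv": "involvement",
                     "start": "start_date"},
            "reac": {"id": "case_id", "ae_name": "pt", "onset": "onset_date",
                     "result": "outcome"},
            "hist": {"id": "case_id", "dz": "disease"},
        },
        involvement_codes={"1": "suspect", "2": "concomitant", "3": "interacting"},
        outcome_labels={"kaifuku": "recovered", "shibou": "death"},
        sex_labels={"F": "female", "M": "male"},
    )
    (tmp_path / "demo.csv").write_text("id,gender\nA,F\n")
    (tmp_path / "drug.csv").write_text("id,generic,inv,start\nA,drugX,1,20200110\nA,drugY,2,\n")
    (tmp_path / "reac.csv").write_text("id,ae_name,onset,result\nA,pt1,202001,kaifuku\nA,pt2,,weird\n")
    (tmp_path / "hist.csv").write_text("id,dz\nA,oc\n")
    paths = {t: tmp_path / f"{t}.csv" for t in ("demo", "drug", "reac", "hist")}
    db = read_tables(paths, dialect)
    assert list(db.drug.involvement) == ["suspect", "concomitant"]
    assert db.demo.sex.item() == "female"
    assert list(db.reac.outcome) == ["recovered", "missing"]  # unmapped -> missing
    assert db.reac.onset_date.iloc[0] == "2020-01"
    # row counts preserved
    assert db.row_counts() == {"demo": 1, "drug": 2, "reac": 2, "hist": 1}


def test_roundtrip_write_read_identity(tmp_path, tiny_db):
    paths = _write_db(tiny_db, tmp_path)
    db1 = read_tables(paths)
    paths2 = {t: tmp_path / f"rt_{t}.csv" for t in ("demo", "drug", "reac", "hist")}
    write_tables(db1, paths2)
    db2 = read_tables(paths2)
    for t in ("demo", "drug", "reac", "hist"):
        pd.testing.assert_frame_equal(db1.table(t), db2.table(t))


def test_roundtrip_on_synthetic_database(tmp_path):
    db, _ = generate(default_config(n_cases=400, seed=5))
    paths = _write_db(db, tmp_path)
    db1 = read_tables(paths)
    for t in ("demo", "drug", "reac", "hist"):
        pd.testing.assert_frame_equal(db.table(t), db1.table(t))


def test_link_cases_joins_and_collects_orphans(tiny_db):
    cases, orphans = link_cases(tiny_db)
    assert [c.case_id for c in cases] == ["A", "B", "C"]
    by_id = {c.case_id: c for c in cases}
    assert len(by_id["A"].drugs) == 3
    assert len(by_id["A"].reactions) == 3
    assert len(by_id["A"].history) == 1
    assert orphans.counts == {"drug": 0, "reac": 1, "hist": 0}
    assert list(orphans.reac.case_id) == ["Z"]
    # conservation: reactions across cases + orphans == REAC rows
    total = sum(len(c.reactions) for c in cases) + len(orphans.reac)
    assert total == len(tiny_db.reac)


def test_link_cases_conservation_on_synthetic(small_synth):
    db, ledger = small_synth
    cases, orphans = link_cases(db)
    assert len(cases) == ledger["n_cases"]
    total = sum(len(c.reactions) for c in cases) + len(orphans.reac)
    assert total == ledger["totals"]["reac_rows"]
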