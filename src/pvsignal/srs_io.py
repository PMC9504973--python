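"""Reading, writing and linking JADER-schema spontaneous-report tables.

A spontaneous reporting system (SRS) database in the JADER layout consists of
four CSV tables keyed by a shared case identification number:

* ``demo`` -- one row per case: sex, age band, reporting period;
* ``drug`` -- one row per reported drug administration: generic name,
  involvement (suspect / concomitant / interacting), start and end dates;
* ``reac`` -- one row per reported adverse event: MedDRA preferred term (PT,
  treated here as an opaque string), onset date, outcome;
* ``hist`` -- one row per underlying disease.

Real-world SRS dates are frequently partial (year-month or year only) or
missing altogether.  They are kept at whatever precision they were reported
at (:class:`PartialDate`); downstream analyses decide usability.

Column headers, coded values (involvement codes, outcome labels, sex labels)
and the character encoding differ between the real download and synthetic
fixtures, so all of that is carried by a :class:`CsvDialect` rather than by
code.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PartialDate",
    "CsvDialect",
    "Database",
    "DemoRecord",
    "DrugRecord",
    "ReacRecord",
    "HistRecord",
    "CaseRecord",
    "OrphanReport",
    "SchemaError",
    "read_tables",
    "write_tables",
    "link_cases",
]

TABLES = ("demo", "drug", "reac", "hist")

#: canonical column sets, post-dialect-mapping
CANONICAL_COLUMNS = {
    "demo": ["case_id", "sex", "age_band", "report_period"],
    "drug": ["case_id", "drug_name", "involvement", "start_date", "end_date", "route"],
    "reac": ["case_id", "pt", "onset_date", "outcome"],
    "hist": ["case_id", "disease"],
}

#: columns that must be present in the input file (after renaming)
MANDATORY_COLUMNS = {
    "demo": ["case_id"],
    "drug": ["case_id", "drug_name"],
    "reac": ["case_id", "pt"],
    "hist": ["case_id"],
}

INVOLVEMENT_VALUES = ("suspect", "concomitant", "interacting", "unknown")
OUTCOME_VALUES = (
    "recovered",
    "remission",
    "not_recovered",
    "with_sequelae",
    "death",
    "unclear",
    "missing",
)
SEX_VALUES = ("female", "male", "unknown")

_DATE_COLUMNS = {
    "drug": ["start_date", "end_date"],
    "reac": ["onset_date"],
}


class SchemaError(ValueError):
    """An input table is missing a mandatory column."""


# ---------------------------------------------------------------------------
# Partial dates
# ---------------------------------------------------------------------------

_PRECISION_RANK = {"day": 3, "month": 2, "year": 1, "missing": 0}


@dataclass(frozen=True)
class PartialDate:
    """A calendar date known to day, month, year precision, or not at all.

    ``precision='day'`` guarantees a valid calendar date; lower precisions
    carry only the fields that were reported.  Ordering of precision is
    day > month > year > missing.
    """

    year: int | None = None
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.year is None and (self.month is not None or self.day is not None):
            raise ValueError("month/day without year")
        if self.month is None and self.day is not None:
            raise ValueError("day without month")

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        if self.year is not None:
            return "year"
        return "missing"

    @property
    def precision_rank(self) -> int:
        return _PRECISION_RANK[self.precision]

    @classmethod
    def parse(cls, text: str | None) -> "PartialDate":
        """Parse ``YYYYMMDD`` / ``YYYY-MM-DD`` style strings, degrading
        gracefully: an invalid day drops to month precision, an invalid
        month to year precision, anything else to missing.  Never raises.
        """
        if text is None:
            return cls()
        s = str(text).strip().replace("/", "-")
        if not s or s.lower() in {"nan", "none", "na"}:
            return cls()
        digits = s.replace("-", "")
        if not digits.isdigit() or len(digits) < 4:
            return cls()
        year = int(digits[:4])
        if not 1000 <= year <= 2999:
            return cls()
        month = int(digits[4:6]) if len(digits) >= 6 else None
        day = int(digits[6:8]) if len(digits) >= 8 else None
        if month is not None and not 1 <= month <= 12:
            return cls(year=year)
        if day is not None:
            try:
                dt.date(year, month, day)
            except ValueError:
                return cls(year=year, month=month)
        return cls(year=year, month=month, day=day)

    def isoformat(self) -> str:
        """Canonical string form: '', 'YYYY', 'YYYY-MM' or 'YYYY-MM-DD'."""
        if self.year is None:
            return ""
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"

    def compact(self) -> str:
        """JADER-style digits-only form: '', 'YYYY', 'YYYYMM' or 'YYYYMMDD'."""
        return self.isoformat().replace("-", "")

    def to_date(self) -> dt.date:
        if self.precision != "day":
            raise ValueError(f"not a day-precision date: {self!r}")
        return dt.date(self.year, self.month, self.day)

    def sort_key(self) -> tuple:
        # complete dates first within a given prefix; missing sorts last
        return (self.year is None, self.isoformat())

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat() or "missing"


def iso_precision(iso: str) -> str:
    """Precision of a canonical partial-date string."""
    return {10: "day", 7: "month", 4: "year", 0: "missing"}.get(len(iso), "missing")


# ---------------------------------------------------------------------------
# Dialect
# ---------------------------------------------------------------------------


def _identity_columns() -> dict[str, dict[str, str]]:
    return {t: {c: c for c in CANONICAL_COLUMNS[t]} for t in TABLES}


@dataclass
class CsvDialect:
    """How the four CSV files spell columns, coded values and dates.

    ``columns`` maps *file* column names to canonical field names, per table.
    ``involvement_codes`` / ``outcome_labels`` / ``sex_labels`` map file
    values to the canonical vocabularies; unmapped values fall back to
    ``unknown`` (or ``missing`` for outcomes).  The default dialect is the
    identity mapping with UTF-8 and compact (``YYYYMMDD``) dates, which is
    what the synthetic generator writes.
    """

    encoding: str = "utf-8"
    date_format: str = "compact"  # "compact" or "iso"
    columns: dict[str, dict[str, str]] = field(default_factory=_identity_columns)
    involvement_codes: dict[str, str] = field(
        default_factory=lambda: {v: v for v in INVOLVEMENT_VALUES}
    )
    outcome_labels: dict[str, str] = field(
        default_factory=lambda: {v: v for v in OUTCOME_VALUES}
    )
    sex_labels: dict[str, str] = field(default_factory=lambda: {v: v for v in SEX_VALUES})

    @classmethod
    def from_file(cls, path: str | Path) -> "CsvDialect":
        """Load a dialect from a YAML or JSON mapping file."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        base = cls()
        for key in ("encoding", "date_format"):
            if key in data:
                setattr(base, key, data[key])
        for key in ("columns", "involvement_codes", "outcome_labels", "sex_labels"):
            if key in data:
                setattr(base, key, data[key])
        return base

    def format_date(self, iso: str) -> str:
        return iso if self.date_format == "iso" else iso.replace("-", "")

    def _inverse_values(self, mapping: dict[str, str]) -> dict[str, str]:
        inv: dict[str, str] = {}
        for file_value, canonical in mapping.items():
            inv.setdefault(canonical, file_value)
        return inv

    def inverse_involvement(self) -> dict[str, str]:
        return self._inverse_values(self.involvement_codes)

    def inverse_outcome(self) -> dict[str, str]:
        return self._inverse_values(self.outcome_labels)

    def inverse_sex(self) -> dict[str, str]:
        return self._inverse_values(self.sex_labels)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemoRecord:
    case_id: str
    sex: str = "unknown"
    age_band: str = ""
    report_period: str = ""


@dataclass(frozen=True)
class DrugRecord:
    case_id: str
    drug_name: str
    involvement: str = "unknown"
    start_date: PartialDate = field(default_factory=PartialDate)
    end_date: PartialDate = field(default_factory=PartialDate)
    route: str = ""


@dataclass(frozen=True)
class ReacRecord:
    case_id: str
    pt: str
    onset_date: PartialDate = field(default_factory=PartialDate)
    outcome: str = "missing"


@dataclass(frozen=True)
class HistRecord:
    case_id: str
    disease: str = ""


@dataclass
class CaseRecord:
    """Case-centric join of the four tables for one case id."""

    demo: DemoRecord
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[ReacRecord] = field(default_factory=list)
    history: list[HistRecord] = field(default_factory=list)

    @property
    def case_id(self) -> str:
        return self.demo.case_id


@dataclass
class OrphanReport:
    """Rows whose case id never appears in DEMO (kept, not dropped)."""

    drug: pd.DataFrame
    reac: pd.DataFrame
    hist: pd.DataFrame

    @property
    def counts(self) -> dict[str, int]:
        return {"drug": len(self.drug), "reac": len(self.reac), "hist": len(self.hist)}

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class Database:
    """The four tables in canonical form.

    All values are strings; dates are canonical partial-date strings
    (``''``, ``'YYYY'``, ``'YYYY-MM'``, ``'YYYY-MM-DD'``); involvement,
    outcome and sex use the canonical vocabularies.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    hist: pd.DataFrame

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def row_counts(self) -> dict[str, int]:
        return {t: len(self.table(t)) for t in TABLES}

    @classmethod
    def empty(cls) -> "Database":
        return cls(
            **{t: pd.DataFrame(columns=CANONICAL_COLUMNS[t], dtype=str) for t in TABLES}
        )


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------


def _map_values(series: pd.Series, mapping: dict[str, str], default: str) -> pd.Series:
    lut = {k: mapping.get(k, default) for k in series.unique()}
    for k in list(lut):
        if str(k).strip() == "":
            lut[k] = "missing" if default == "missing" else default
    return series.map(lut)


def _normalize_dates(series: pd.Series) -> pd.Series:
    lut = {v: PartialDate.parse(v).isoformat() for v in series.unique()}
    return series.map(lut)


def read_tables(
    paths: Mapping[str, str | Path], dialect: CsvDialect | None = None
) -> Database:
    """Read the four CSV tables into a canonical :class:`Database`.

    Every input row becomes exactly one canonical row; unparseable dates are
    degraded in precision, never fatal.  A missing file raises
    ``FileNotFoundError`` naming the table; a missing mandatory column raises
    :class:`SchemaError` naming the column.
    """
    dialect = dialect or CsvDialect()
    frames: dict[str, pd.DataFrame] = {}
    for tbl in TABLES:
        if tbl not in paths:
            raise FileNotFoundError(f"no path given for table '{tbl}'")
        path = Path(paths[tbl])
        if not path.exists():
            raise FileNotFoundError(f"table '{tbl}': file not found: {path}")
        df = pd.read_csv(
            path, dtype=str, keep_default_na=False, encoding=dialect.encoding
        )
        df = df.rename(columns=dialect.columns.get(tbl, {}))
        for col in MANDATORY_COLUMNS[tbl]:
            if col not in df.columns:
                raise SchemaError(f"table '{tbl}': missing mandatory column '{col}'")
        for col in CANONICAL_COLUMNS[tbl]:
            if col not in df.columns:
                df[col] = ""
        df = df[CANONICAL_COLUMNS[tbl]].copy()
        for col in _DATE_COLUMNS.get(tbl, []):
            df[col] = _normalize_dates(df[col])
        if tbl == "demo" and len(df):
            df["sex"] = _map_values(df["sex"], dialect.sex_labels, "unknown")
        if tbl == "drug" and len(df):
            df["involvement"] = _map_values(
                df["involvement"], dialect.involvement_codes, "unknown"
            )
        if tbl == "reac" and len(df):
            df["outcome"] = _map_values(df["outcome"], dialect.outcome_labels, "missing")
        frames[tbl] = df
    return Database(**frames)


def write_tables(
    db: Database, paths: Mapping[str, str | Path], dialect: CsvDialect | None = None
) -> None:
    """Write a canonical database back to four CSV files in ``dialect`` form.

    Inverse of :func:`read_tables` for round-trippable dialects (value maps
    that are right-invertible on the canonical vocabularies).
    """
    dialect = dialect or CsvDialect()
    inverses = {
        ("demo", "sex"): dialect.inverse_sex(),
        ("drug", "involvement"): dialect.inverse_involvement(),
        ("reac", "outcome"): dialect.inverse_outcome(),
    }
    for tbl in TABLES:
        df = db.table(tbl).copy()
        for col in _DATE_COLUMNS.get(tbl, []):
            df[col] = df[col].map(dialect.format_date)
        for (t, col), mapping in inverses.items():
            if t == tbl and len(df):
                df[col] = df[col].map(lambda v: mapping.get(v, v))
        rename = {canon: file_col for file_col, canon in dialect.columns.get(tbl, {}).items()}
        df = df.rename(columns=rename)
        df.to_csv(paths[tbl], index=False, encoding=dialect.encoding, lineterminator="\n")


# ---------------------------------------------------------------------------
# Record conversion and linkage
# ---------------------------------------------------------------------------


def _demo_record(row) -> DemoRecord:
    return DemoRecord(
        case_id=row.case_id, sex=row.sex, age_band=row.age_band,
        report_period=row.report_period,
    )


def _drug_record(row) -> DrugRecord:
    return DrugRecord(
        case_id=row.case_id,
        drug_name=row.drug_name,
        involvement=row.involvement,
        start_date=PartialDate.parse(row.start_date),
        end_date=PartialDate.parse(row.end_date),
        route=row.route,
    )


def _reac_record(row) -> ReacRecord:
    return ReacRecord(
        case_id=row.case_id,
        pt=row.pt,
        onset_date=PartialDate.parse(row.onset_date),
        outcome=row.outcome,
    )


def link_cases(db: Database) -> tuple[list[CaseRecord], OrphanReport]:
    """Join the four tables into one :class:`CaseRecord` per DEMO case id.

    DRUG/REAC/HIST rows whose case id is absent from DEMO are returned in the
    :class:`OrphanReport` rather than silently dropped.
    """
    known = set(db.demo["case_id"])
    orphans = OrphanReport(
        drug=db.drug[~db.drug["case_id"].isin(known)].copy(),
        reac=db.reac[~db.reac["case_id"].isin(known)].copy(),
        hist=db.hist[~db.hist["case_id"].isin(known)].copy(),
    )
    cases: dict[str, CaseRecord] = {}
    for row in db.demo.itertuples(index=False):
        cases[row.case_id] = CaseRecord(demo=_demo_record(row))
    for row in db.drug.itertuples(index=False):
        case = cases.get(row.case_id)
        if case is not None:
            case.drugs.append(_drug_record(row))
    for row in db.reac.itertuples(index=False):
        case = cases.get(row.case_id)
        if case is not None:
            case.reactions.append(_reac_record(row))
    for row in db.hist.itertuples(index=False):
        case = cases.get(row.case_id)
        if case is not None:
            case.history.append(HistRecord(case_id=row.case_id, disease=row.disease))
    return list(cases.values()), orphans


def cases_to_database(cases: Iterable[CaseRecord]) -> Database:
    """Flatten CaseRecords back into a canonical :class:`Database`."""
    demo_rows, drug_rows, reac_rows, hist_rows = [], [], [], []
    for case in cases:
        demo_rows.append(dataclasses.asdict(case.demo))
        for d in case.drugs:
            drug_rows.append(
                {
                    "case_id": d.case_id,
                    "drug_name": d.drug_name,
                    "involvement": d.involvement,
                    "start_date": d.start_date.isoformat(),
                    "end_date": d.end_date.isoformat(),
                    "route": d.route,
                }
            )
        for r in case.reactions:
            reac_rows.append(
                {
                    "case_id": r.case_id,
                    "pt": r.pt,
                    "onset_date": r.onset_date.isoformat(),
                    "outcome": r.outcome,
                }
            )
        for h in case.history:
            hist_rows.append({"case_id": h.case_id, "disease": h.disease})

    def frame(rows, tbl):
        if not rows:
            return pd.DataFrame(columns=CANONICAL_COLUMNS[tbl], dtype=str)
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS[tbl]).astype(str)

    return Database(
        demo=frame(demo_rows, "demo"),
        drug=frame(drug_rows, "drug"),
        reac=frame(reac_rows, "reac"),
        hist=frame(hist_rows, "hist"),
    )
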