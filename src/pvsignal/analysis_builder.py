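"""Build the (case, drug, event) unit-of-analysis table.

All downstream statistics count *case-PT pairs*: one row per distinct
(case id, drug name, preferred term) combination.  A case therefore
contributes at most 1 to any single drug-event cell no matter how many times
the drug was re-administered or the PT re-reported within it.  With the
default ``suspect_only=True`` only drugs coded as suspect contribute pairs,
matching how disproportionality contingency tables condition on the suspect
drug.

When several REAC rows of one case share a PT, the retained row carries the
worst outcome (death > with sequelae > not recovered > remission > recovered
> unclear; missing lowest) and the best-precision, earliest onset date.
"""

from __future__ import annotations

from typing import Iterable, Union

import pandas as pd

from .srs_io import CaseRecord, Database, cases_to_database, iso_precision

__all__ = ["PAIR_COLUMNS", "build_pairs", "count_events", "pairs_to_tsv", "pairs_from_tsv"]

PAIR_COLUMNS = [
    "case_id",
    "drug_name",
    "pt",
    "involvement",
    "onset_date",
    "outcome",
    "start_dates",
]

#: worst-first severity ranking for outcome dedup
OUTCOME_SEVERITY = {
    "death": 6,
    "with_sequelae": 5,
    "not_recovered": 4,
    "remission": 3,
    "recovered": 2,
    "unclear": 1,
    "missing": 0,
}

_INVOLVEMENT_PREF = {"suspect": 0, "interacting": 1, "concomitant": 2, "unknown": 3}


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(columns=PAIR_COLUMNS)


def _start_sort_key(iso: str) -> tuple:
    return (iso == "", iso)


def _dedup_drug(drug: pd.DataFrame) -> pd.DataFrame:
    """One row per (case, drug) with all start dates gathered and sorted."""
    df = drug.copy()
    # '~' sorts after any date digit, pushing missing dates to the end
    df["_sk"] = df["start_date"].where(df["start_date"] != "", "~")
    df["_ip"] = df["involvement"].map(lambda v: _INVOLVEMENT_PREF.get(v, 9))
    df = df.sort_values(["case_id", "drug_name", "_sk"], kind="mergesort")
    grouped = df.groupby(["case_id", "drug_name"], sort=False)
    starts = grouped["start_date"].agg(tuple)
    involvement = df.sort_values(["case_id", "drug_name", "_ip"], kind="mergesort") \
        .drop_duplicates(["case_id", "drug_name"]).set_index(["case_id", "drug_name"])["involvement"]
    out = pd.DataFrame({"start_dates": starts, "involvement": involvement}).reset_index()
    return out


def _dedup_reac(reac: pd.DataFrame) -> pd.DataFrame:
    """One row per (case, pt): worst outcome, best-precision earliest onset."""
    df = reac.copy()
    df["_sev"] = df["outcome"].map(lambda v: OUTCOME_SEVERITY.get(v, 0))
    df["_prec"] = df["onset_date"].map(lambda v: -{"day": 3, "month": 2, "year": 1}.get(iso_precision(v), 0))
    worst = (
        df.sort_values(["case_id", "pt", "_sev"], ascending=[True, True, False])
        .drop_duplicates(["case_id", "pt"])[["case_id", "pt", "outcome"]]
    )
    onset = (
        df.sort_values(["case_id", "pt", "_prec", "onset_date"])
        .drop_duplicates(["case_id", "pt"])[["case_id", "pt", "onset_date"]]
    )
    return worst.merge(onset, on=["case_id", "pt"])


def build_pairs(
    source: Union[Database, Iterable[CaseRecord], pd.DataFrame],
    suspect_only: bool = True,
) -> pd.DataFrame:
    """Build the deduplicated pair table.

    ``source`` may be a :class:`~pvsignal.srs_io.Database`, an iterable of
    :class:`~pvsignal.srs_io.CaseRecord`, or an existing pair table (in which
    case the canonical dedup/sort is a fixed point).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        if suspect_only:
            df = df[df["involvement"] == "suspect"]
        df = df.drop_duplicates(["case_id", "drug_name", "pt"])
        return (
            df.sort_values(["case_id", "drug_name", "pt"], kind="mergesort")
            .reset_index(drop=True)[PAIR_COLUMNS]
        )
    if not isinstance(source, Database):
        source = cases_to_database(source)
    drug = source.drug
    if suspect_only:
        drug = drug[drug["involvement"] == "suspect"]
    if drug.empty or source.reac.empty:
        return _empty_pairs()
    drug_u = _dedup_drug(drug)
    reac_u = _dedup_reac(source.reac)
    pairs = drug_u.merge(reac_u, on="case_id", how="inner")
    pairs = pairs.sort_values(["case_id", "drug_name", "pt"], kind="mergesort")
    return pairs.reset_index(drop=True)[PAIR_COLUMNS]


def count_events(pairs: pd.DataFrame, drug: str) -> pd.DataFrame:
    """Distinct-case counts per PT for one drug (columns ``pt``, ``cases``).

    An unknown drug yields an empty table.
    """
    sub = pairs[pairs["drug_name"] == drug]
    if sub.empty:
        return pd.DataFrame(columns=["pt", "cases"])
    counts = sub.groupby("pt").size().rename("cases").reset_index()
    return (
        counts.sort_values(["cases", "pt"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def pairs_to_tsv(pairs: pd.DataFrame, path) -> None:
    """Serialize the pair table (start dates ';'-joined), deterministic order."""
    out = pairs.copy()
    out["start_dates"] = out["start_dates"].map(lambda t: ";".join(t))
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def pairs_from_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["start_dates"] = df["start_dates"].map(lambda s: tuple(s.split(";")))
    return df[PAIR_COLUMNS]
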