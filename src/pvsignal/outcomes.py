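"""Post-event outcome tabulation per drug-event pair.

Each pair carries one of six outcome categories (recovered, remission, not
recovered, with sequelae, death, unclear) or ``missing``.  Tabulation drops
missing-outcome pairs from the denominator -- the published convention of
analysing "data for which information on outcomes was reported" -- which is
why an outcome table's n can be smaller than the signal table's case count.
Percentages are computed exactly (rational arithmetic) and rounded half-up
to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .srs_io import OUTCOME_VALUES

__all__ = ["OUTCOME_CATEGORIES", "OutcomeSummary", "pct_half_up", "tabulate_outcomes", "outcomes_table"]

#: the six reportable categories, in published column order
OUTCOME_CATEGORIES = [v for v in OUTCOME_VALUES if v != "missing"]


@dataclass(frozen=True)
class OutcomeSummary:
    drug: str
    pt: str
    n: int
    counts: dict
    percents: dict


def pct_half_up(count: int, n: int) -> float:
    """``100*count/n`` rounded half-up to one decimal, exactly."""
    if n == 0:
        raise ZeroDivisionError("empty denominator")
    pct = Decimal(100 * int(count)) / Decimal(int(n))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tabulate_outcomes(pairs: pd.DataFrame, drug: str, pts) -> list[OutcomeSummary]:
    """One :class:`OutcomeSummary` per requested PT for ``drug``.

    ``pts`` is typically the list of signal-flagged PTs.  A PT with no
    outcome-bearing pairs yields ``n=0`` with empty percents.
    """
    sub = pairs[(pairs["drug_name"] == drug) & (pairs["outcome"] != "missing")]
    summaries = []
    for pt in pts:
        outcome_counts = sub.loc[sub["pt"] == pt, "outcome"].value_counts()
        counts = {cat: int(outcome_counts.get(cat, 0)) for cat in OUTCOME_CATEGORIES}
        n = sum(counts.values())
        percents = {cat: pct_half_up(c, n) for cat, c in counts.items()} if n else {}
        summaries.append(OutcomeSummary(drug=drug, pt=pt, n=n, counts=counts, percents=percents))
    return summaries


def outcomes_table(summaries) -> pd.DataFrame:
    """Published-style layout: one row per PT, 'count (pct%)' cells."""
    rows = []
    for s in summaries:
        row = {"drug": s.drug, "pt": s.pt, "n": s.n}
        for cat in OUTCOME_CATEGORIES:
            if s.n:
                row[cat] = f"{s.counts[cat]} ({s.percents[cat]:.1f}%)"
            else:
                row[cat] = ""
        rows.append(row)
    return pd.DataFrame(rows, columns=["drug", "pt", "n", *OUTCOME_CATEGORIES])
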