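"""Reporting odds ratio (ROR) disproportionality analysis.

For a target drug D and event E, reports (case-PT pairs) are cross-classified
into the 2x2 contingency table

    a = pairs with D and E          b = pairs with D, other events
    c = pairs with E, other drugs   d = pairs with neither

and the reporting odds ratio is ROR = (a*d)/(b*c).  The 95% confidence
interval uses Woolf's log-normal method,

    exp( ln ROR +/- z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d) ),

with the Haldane-Anscombe continuity correction (+0.5 on every cell, applied
to both the point estimate and the CI) engaged only when some cell is zero.
A signal is declared when the lower CI limit exceeds 1 and the pair clears a
minimum-case screen (default 10 reports), a standard hypothesis-generating
rule for spontaneous-report data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "RorEstimate",
    "contingency",
    "ror_estimate",
    "detect_signals",
    "apply_signal_rule",
    "format_signals",
]

SIGNAL_COLUMNS = [
    "drug",
    "pt",
    "cases",
    "non_cases",
    "rate_pct",
    "ror",
    "ci_low",
    "ci_high",
    "is_signal",
    "screened_out",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts for one (drug, event) pair over the whole pair table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RorEstimate:
    ror: float
    ci_low: float
    ci_high: float


def contingency(pairs: pd.DataFrame, drug: str, pt: str) -> ContingencyTable:
    """2x2 table for (drug, pt) under the case-PT pair counting unit."""
    is_drug = pairs["drug_name"] == drug
    is_pt = pairs["pt"] == pt
    a = int((is_drug & is_pt).sum())
    b = int((is_drug & ~is_pt).sum())
    c = int((~is_drug & is_pt).sum())
    d = int((~is_drug & ~is_pt).sum())
    return ContingencyTable(a, b, c, d)


def _ror_arrays(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    z: float,
    zero_cell_policy: str = "haldane",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    if zero_cell_policy == "haldane":
        needs = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        a, b, c, d = (x + 0.5 * needs for x in (a, b, c, d))
    elif zero_cell_policy != "none":
        raise ValueError(f"unknown zero_cell_policy: {zero_cell_policy!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ror = np.log(a) + np.log(d) - np.log(b) - np.log(c)
        se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return np.exp(log_ror), np.exp(log_ror - z * se), np.exp(log_ror + z * se)


def ror_estimate(
    table: ContingencyTable,
    alpha_level: float = 0.05,
    zero_cell_policy: str = "haldane",
) -> RorEstimate:
    """Point estimate and Woolf CI for one contingency table.

    Raises ``ValueError`` when every cell is zero (no information at all).
    """
    if table.total == 0:
        raise ValueError("undefined ROR: all contingency cells are zero")
    z = stats.norm.ppf(1.0 - alpha_level / 2.0)
    ror, lo, hi = _ror_arrays(
        np.array([table.a]),
        np.array([table.b]),
        np.array([table.c]),
        np.array([table.d]),
        z,
        zero_cell_policy,
    )
    return RorEstimate(float(ror[0]), float(lo[0]), float(hi[0]))


def detect_signals(
    pairs: pd.DataFrame,
    drug: str,
    min_cases: int = 10,
    alpha_level: float = 0.05,
    zero_cell_policy: str = "haldane",
) -> pd.DataFrame:
    """ROR signal screen for every PT observed with ``drug``.

    Pairs below ``min_cases`` are flagged ``screened_out`` and can never be
    signals; all rows still carry their estimates.  Result sorted by ROR
    descending (PT ascending as tie-break).
    """
    sub = pairs[pairs["drug_name"] == drug]
    if sub.empty:
        return pd.DataFrame(columns=SIGNAL_COLUMNS)
    n_total = len(pairs)
    n_drug = len(sub)
    pt_counts_drug = sub.groupby("pt").size()
    pt_counts_all = pairs.groupby("pt").size()
    pts = pt_counts_drug.index.to_numpy()
    a = pt_counts_drug.to_numpy(dtype=np.int64)
    b = n_drug - a
    c = pt_counts_all.reindex(pts).to_numpy(dtype=np.int64) - a
    d = n_total - a - b - c
    z = stats.norm.ppf(1.0 - alpha_level / 2.0)
    ror, lo, hi = _ror_arrays(a, b, c, d, z, zero_cell_policy)
    screened = a < min_cases
    out = pd.DataFrame(
        {
            "drug": drug,
            "pt": pts,
            "cases": a,
            "non_cases": b,
            "rate_pct": 100.0 * a / n_drug,
            "ror": ror,
            "ci_low": lo,
            "ci_high": hi,
            "is_signal": (lo > 1.0) & ~screened,
            "screened_out": screened,
        }
    )
    return (
        out.sort_values(["ror", "pt"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)[SIGNAL_COLUMNS]
    )


def apply_signal_rule(
    ci_low: pd.Series | np.ndarray, cases: pd.Series | np.ndarray, min_cases: int = 10
) -> np.ndarray:
    """Vectorized signal rule: lower CI limit > 1 and cases >= min_cases.

    Useful for re-applying the rule to externally published estimate tables.
    """
    return (np.asarray(ci_low, dtype=float) > 1.0) & (
        np.asarray(cases, dtype=np.int64) >= min_cases
    )


def format_signals(signals: pd.DataFrame) -> pd.DataFrame:
    """Display formatting: rates/ROR/CI rounded to 2 decimals, CI as text."""
    out = signals.copy()
    for col in ("rate_pct", "ror", "ci_low", "ci_high"):
        out[col] = out[col].map(lambda v: float(f"{v:.2f}") if math.isfinite(v) else v)
    out["ror_95ci"] = [
        f"{r:.2f} ({lo:.2f}-{hi:.2f})"
        for r, lo, hi in zip(out["ror"], out["ci_low"], out["ci_high"])
    ]
    return out
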