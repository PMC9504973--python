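"""Published JADER PARP-inhibitor results, transcribed for reanalysis.

These tables transcribe the results of a published JADER disproportionality
study of the PARP inhibitors olaparib and niraparib (reports April 2004 to
December 2021; 1,552 olaparib and 549 niraparib adverse-event reports out of
1,890,222 total).  They serve as regression fixtures: the raw case-level
JADER download is not redistributable, but the printed per-pair counts,
rates, ROR confidence intervals, outcome counts and Weibull parameters are
enough to re-verify the pipeline's arithmetic, signal rule, rounding and
failure-type classification.

Abbreviated PT spellings follow the source: MDS = myelodysplastic syndrome,
AML = acute myeloid leukaemia, ILD = interstitial lung disease.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "OLAPARIB_TOTAL_REPORTS",
    "NIRAPARIB_TOTAL_REPORTS",
    "GRAND_TOTAL_REPORTS",
    "signal_table",
    "outcome_table",
    "weibull_table",
]

OLAPARIB_TOTAL_REPORTS = 1552
NIRAPARIB_TOTAL_REPORTS = 549
GRAND_TOTAL_REPORTS = 1_890_222

# drug, pt, cases, non_cases, rate_pct, ror, ci_low, ci_high
_SIGNAL_ROWS = [
    ("olaparib", "Malignant neoplasm progression", 242, 1310, 15.59, 73.50, 63.90, 84.55),
    ("olaparib", "Anaemia", 496, 1056, 31.96, 40.50, 36.37, 45.09),
    ("olaparib", "Myelodysplastic syndrome", 30, 1522, 1.93, 11.71, 8.15, 16.84),
    ("olaparib", "Fatigue", 10, 1542, 0.64, 6.46, 3.47, 12.06),
    ("olaparib", "Acute myeloid leukaemia", 12, 1540, 0.77, 6.33, 3.58, 11.18),
    ("olaparib", "Ileus", 14, 1538, 0.90, 5.24, 3.09, 8.88),
    ("olaparib", "Myelosuppression", 33, 1519, 2.13, 3.83, 2.71, 5.40),
    ("olaparib", "Nausea", 34, 1518, 2.19, 3.47, 2.47, 4.88),
    ("olaparib", "Neutrophil count decreased", 63, 1489, 4.06, 2.85, 2.21, 3.67),
    ("olaparib", "Interstitial lung disease", 90, 1462, 5.80, 2.19, 1.77, 2.71),
    ("olaparib", "Malaise", 15, 1537, 0.97, 2.03, 1.22, 3.38),
    ("olaparib", "Pancytopenia", 20, 1532, 1.29, 2.02, 1.30, 3.14),
    ("olaparib", "Death", 14, 1538, 0.90, 1.87, 1.10, 3.17),
    ("olaparib", "Platelet count decreased", 49, 1503, 3.16, 1.83, 1.38, 2.43),
    ("olaparib", "Vomiting", 15, 1537, 0.97, 1.77, 1.06, 2.95),
    ("olaparib", "Neutropenia", 24, 1528, 1.55, 1.38, 0.92, 2.06),
    ("olaparib", "Haemoglobin decreased", 11, 1541, 0.71, 1.35, 0.75, 2.44),
    ("olaparib", "Renal impairment", 17, 1535, 1.10, 1.02, 0.63, 1.65),
    ("olaparib", "Decreased appetite", 11, 1541, 0.71, 0.93, 0.51, 1.68),
    ("olaparib", "Pyrexia", 17, 1535, 1.10, 0.79, 0.49, 1.27),
    ("olaparib", "Febrile neutropenia", 12, 1540, 0.77, 0.74, 0.42, 1.31),
    ("olaparib", "White blood cell count decreased", 14, 1538, 0.90, 0.67, 0.40, 1.14),
    ("niraparib", "Ovarian cancer recurrent", 26, 523, 4.74, 1917.13, 1182.47, 3108.217),
    ("niraparib", "Ovarian cancer", 35, 514, 6.38, 500.61, 348.02, 720.11),
    ("niraparib", "Disease progression", 57, 492, 10.38, 101.85, 77.17, 134.42),
    ("niraparib", "Thrombocytopenia", 44, 505, 8.01, 13.60, 9.99, 18.52),
    ("niraparib", "Ileus", 11, 538, 2.00, 11.99, 6.60, 21.80),
    ("niraparib", "Condition aggravated", 10, 539, 1.82, 10.11, 5.40, 18.91),
    ("niraparib", "Platelet count decreased", 75, 474, 13.66, 8.90, 6.98, 11.35),
    ("niraparib", "Renal impairment", 41, 508, 7.47, 7.45, 5.42, 10.24),
    ("niraparib", "Anaemia", 39, 510, 7.10, 6.46, 4.66, 8.95),
    ("niraparib", "Myelosuppression", 15, 534, 2.73, 4.94, 2.96, 8.26),
    ("niraparib", "Neutrophil count decreased", 25, 524, 4.55, 3.21, 2.15, 4.80),
]

# drug, pt, n, then (count, printed %) per category:
# recovered, remission, not_recovered, with_sequelae, death, unclear
_OUTCOME_ROWS = [
    ("olaparib", "Anaemia", 496, (223, 45.0), (93, 18.8), (46, 9.2), (0, 0.0), (1, 0.2), (133, 26.8)),
    ("olaparib", "Myelodysplastic syndrome", 30, (0, 0.0), (1, 3.3), (14, 46.7), (0, 0.0), (8, 26.7), (7, 23.3)),
    ("olaparib", "Acute myeloid leukaemia", 12, (0, 0.0), (0, 0.0), (3, 25.0), (0, 0.0), (6, 50.0), (3, 25.0)),
    ("olaparib", "Myelosuppression", 33, (12, 36.3), (2, 6.1), (2, 6.1), (0, 0.0), (0, 0.0), (17, 51.5)),
    ("olaparib", "Neutrophil count decreased", 63, (23, 36.5), (8, 12.7), (3, 4.8), (0, 0.0), (0, 0.0), (29, 46.0)),
    ("olaparib", "Platelet count decreased", 49, (26, 53.1), (8, 16.3), (3, 6.1), (0, 0.0), (2, 4.1), (10, 20.4)),
    ("olaparib", "Pancytopenia", 20, (8, 40.0), (4, 20.0), (1, 5.0), (0, 0.0), (0, 0.0), (7, 35.0)),
    ("olaparib", "Ileus", 14, (2, 14.3), (1, 7.1), (1, 7.1), (0, 0.0), (0, 0.0), (10, 71.5)),
    ("olaparib", "Nausea", 34, (14, 41.2), (6, 17.6), (7, 20.6), (0, 0.0), (0, 0.0), (7, 20.6)),
    ("olaparib", "Vomiting", 15, (6, 40.0), (4, 26.7), (2, 13.3), (0, 0.0), (0, 0.0), (3, 20.0)),
    ("olaparib", "Malignant neoplasm progression", 242, (0, 0.0), (0, 0.0), (1, 0.4), (0, 0.0), (32, 13.2), (209, 86.4)),
    ("olaparib", "Fatigue", 5, (4, 80.0), (0, 0.0), (1, 20.0), (0, 0.0), (0, 0.0), (0, 0.0)),
    ("olaparib", "Interstitial lung disease", 90, (37, 41.1), (31, 34.5), (2, 2.2), (2, 2.2), (0, 0.0), (18, 20.0)),
    ("olaparib", "Malaise", 15, (7, 46.7), (3, 20.0), (2, 13.3), (0, 0.0), (0, 0.0), (3, 20.0)),
    ("olaparib", "Death", 14, (0, 0.0), (0, 0.0), (0, 0.0), (0, 0.0), (14, 100.0), (0, 0.0)),
    ("niraparib", "Thrombocytopenia", 44, (20, 45.4), (7, 15.9), (8, 18.2), (0, 0.0), (0, 0.0), (9, 20.5)),
    ("niraparib", "Platelet count decreased", 75, (36, 48.0), (13, 17.3), (17, 22.7), (0, 0.0), (0, 0.0), (9, 12.0)),
    ("niraparib", "Anaemia", 39, (14, 35.9), (10, 25.6), (8, 20.5), (0, 0.0), (0, 0.0), (7, 18.0)),
    ("niraparib", "Myelosuppression", 15, (2, 13.3), (1, 6.7), (2, 13.3), (0, 0.0), (0, 0.0), (10, 66.7)),
    ("niraparib", "Neutrophil count decreased", 25, (12, 48.0), (5, 20.0), (6, 24.0), (0, 0.0), (0, 0.0), (2, 8.0)),
    ("niraparib", "Ileus", 11, (3, 27.3), (1, 9.1), (4, 36.3), (0, 0.0), (0, 0.0), (3, 27.3)),
    ("niraparib", "Ovarian cancer recurrent", 26, (1, 3.8), (1, 3.8), (7, 27.0), (0, 0.0), (2, 7.7), (15, 57.7)),
    ("niraparib", "Ovarian cancer", 35, (1, 2.8), (1, 2.8), (15, 42.9), (0, 0.0), (3, 8.6), (15, 42.9)),
    ("niraparib", "Disease progression", 57, (2, 3.5), (3, 3.5), (21, 36.8), (0, 0.0), (4, 7.0), (28, 49.2)),
    ("niraparib", "Condition aggravated", 10, (0, 0.0), (0, 0.0), (4, 40.0), (0, 0.0), (2, 20.0), (4, 40.0)),
    ("niraparib", "Renal impairment", 41, (8, 19.5), (3, 7.3), (13, 31.7), (0, 0.0), (0, 0.0), (17, 41.5)),
]

# drug, pt, n, alpha, alpha_lo, alpha_hi, beta, beta_lo, beta_hi
_WEIBULL_ROWS = [
    ("olaparib", "Anaemia", 327, 84.54, 76.42, 93.39, 1.15, 1.06, 1.24),
    ("olaparib", "Myelodysplastic syndrome", 18, 361.28, 241.26, 527.09, 1.33, 0.88, 1.88),
    ("olaparib", "Acute myeloid leukaemia", 4, 363.24, 181.38, 708.13, 2.06, 0.77, 4.21),
    ("olaparib", "Myelosuppression", 15, 74.67, 40.29, 134.06, 0.96, 0.60, 1.40),
    ("olaparib", "Neutrophil count decreased", 31, 55.16, 33.81, 88.03, 0.80, 0.60, 1.03),
    ("olaparib", "Platelet count decreased", 41, 60.93, 40.87, 89.39, 0.85, 0.67, 1.04),
    ("olaparib", "Pancytopenia", 14, 118.11, 68.90, 196.54, 1.13, 0.74, 1.59),
    ("olaparib", "Ileus", 5, 65.97, 21.34, 193.61, 1.08, 0.45, 2.09),
    ("olaparib", "Nausea", 27, 9.60, 4.39, 20.21, 0.54, 0.41, 0.70),
    ("olaparib", "Vomiting", 14, 6.68, 2.04, 20.49, 0.51, 0.34, 0.72),
    ("olaparib", "Malignant neoplasm progression", 24, 187.71, 134.30, 257.64, 1.35, 0.97, 1.81),
    ("olaparib", "Fatigue", 8, 34.74, 14.52, 79.09, 0.98, 0.53, 1.57),
    ("olaparib", "Interstitial lung disease", 67, 151.25, 126.37, 179.90, 1.46, 1.21, 1.73),
    ("olaparib", "Malaise", 13, 35.78, 13.60, 88.19, 0.67, 0.41, 1.01),
    ("olaparib", "Death", 2, 397.34, 210.89, 772.73, 4.17, 0.91, 11.26),
    ("niraparib", "Thrombocytopenia", 34, 46.55, 32.96, 64.74, 1.08, 0.82, 1.37),
    ("niraparib", "Platelet count decreased", 65, 53.20, 43.52, 64.62, 1.31, 1.07, 1.57),
    ("niraparib", "Anaemia", 30, 49.45, 35.05, 68.73, 1.16, 0.86, 1.50),
    ("niraparib", "Myelosuppression", 8, 57.31, 30.39, 103.86, 1.34, 0.74, 2.11),
    ("niraparib", "Neutrophil count decreased", 23, 47.37, 32.47, 66.99, 1.24, 0.87, 1.67),
    ("niraparib", "Ileus", 10, 53.39, 36.08, 77.07, 1.90, 1.12, 2.88),
    ("niraparib", "Ovarian cancer recurrent", 20, 41.94, 30.03, 57.51, 1.50, 1.05, 2.01),
    ("niraparib", "Ovarian cancer", 28, 67.74, 47.49, 95.05, 1.17, 0.85, 1.53),
    ("niraparib", "Disease progression", 43, 55.77, 42.50, 72.42, 1.21, 0.95, 1.49),
    ("niraparib", "Condition aggravated", 8, 50.81, 29.50, 84.69, 1.56, 0.87, 2.44),
    ("niraparib", "Renal impairment", 32, 46.34, 31.42, 67.17, 0.99, 0.75, 1.27),
]

_OUTCOME_CATEGORIES = (
    "recovered", "remission", "not_recovered", "with_sequelae", "death", "unclear",
)


def signal_table(drug: str | None = None) -> pd.DataFrame:
    """Published per-PT report counts, rates and ROR (95% CI).

    22 olaparib rows and 11 niraparib rows (every PT with >= 10 reports).
    """
    df = pd.DataFrame(
        _SIGNAL_ROWS,
        columns=["drug", "pt", "cases", "non_cases", "rate_pct", "ror", "ci_low", "ci_high"],
    )
    if drug is not None:
        df = df[df["drug"] == drug].reset_index(drop=True)
    return df


def outcome_table(drug: str | None = None) -> pd.DataFrame:
    """Published post-event outcome counts with their printed percentages.

    Long format: one row per (drug, pt, outcome) with ``count`` and
    ``printed_pct``; ``n`` is the outcome-bearing report count for the pair.
    """
    rows = []
    for entry in _OUTCOME_ROWS:
        d, pt, n = entry[0], entry[1], entry[2]
        for cat, (count, pct) in zip(_OUTCOME_CATEGORIES, entry[3:]):
            rows.append((d, pt, n, cat, count, pct))
    df = pd.DataFrame(
        rows, columns=["drug", "pt", "n", "outcome", "count", "printed_pct"]
    )
    if drug is not None:
        df = df[df["drug"] == drug].reset_index(drop=True)
    return df


def weibull_table(drug: str | None = None) -> pd.DataFrame:
    """Published Weibull scale/shape estimates with 95% CIs per pair."""
    df = pd.DataFrame(
        _WEIBULL_ROWS,
        columns=["drug", "pt", "n", "alpha", "alpha_lo", "alpha_hi", "beta", "beta_lo", "beta_hi"],
    )
    if drug is not None:
        df = df[df["drug"] == drug].reset_index(drop=True)
    return df
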