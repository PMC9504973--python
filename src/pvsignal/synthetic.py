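"""Synthetic JADER-schema databases with controlled statistical structure.

The generator emulates the structural features the pipeline must handle --
four linked tables, suspect/concomitant involvement, repeated drug courses,
partial and missing dates, multinomial outcomes -- and plants drug-event
associations whose strength (target reporting odds ratio), onset-delay law
(Weibull scale/shape) and outcome mix are known, so every downstream
statistic can be checked against ground truth.  It makes no attempt to mimic
real marginal adverse-event frequencies or Japanese text fields.

Event mechanics per case: exposure to each drug is an independent Bernoulli
draw; each preferred term occurs with its background probability q, except
that for a planted (drug, pt) pair the probability among suspect-exposed
cases is tilted so that the *expected pair-unit reporting odds ratio* of
the pipeline equals the target.  Writing s for the drug's suspect-exposure
probability, the comparator ("other drugs") cells contain a fraction s of
tilted cases, so the expected ROR is p1 / (q + s*(p1 - q)) up to
vanishing odds corrections; inverting gives the closed-form tilt

    p1 = target_ror * q * (1 - s) / (1 - target_ror * s)

The tilt is infeasible (raises :class:`ConfigError`) when target_ror * s
>= 1 or the resulting p1 falls outside (0, 1).
Onset dates for planted events are the drug's first start date plus a
Weibull(alpha, beta) delay rounded to whole days (real dates have day
resolution; the downstream +0.5 convention restores the half-day offset).
Background events onset an exponential delay after the case's earliest
suspect start.  The returned ledger records the realized a/b/c/d cells for
every planted pair under the same suspect-only case-PT-pair unit the
pipeline counts, so tests can compare exactly.

Identical seed and config give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .published import signal_table
from .srs_io import CsvDialect, Database, write_tables

__all__ = [
    "ConfigError",
    "PlantedAssociation",
    "GeneratorConfig",
    "default_config",
    "generate",
    "write_database",
    "table1_fixture",
]

OUTCOME_DRAW_ORDER = (
    "recovered", "remission", "not_recovered", "with_sequelae",
    "death", "unclear", "missing",
)

DEFAULT_OUTCOME_PROBS = {
    "recovered": 0.35,
    "remission": 0.15,
    "not_recovered": 0.15,
    "with_sequelae": 0.01,
    "death": 0.04,
    "unclear": 0.20,
    "missing": 0.10,
}

_AGE_BANDS = ["40-49", "50-59", "60-69", "70-79", "80-89"]
_AGE_PROBS = [0.10, 0.25, 0.30, 0.25, 0.10]
_DISEASES = ["ovarian cancer", "breast cancer", "prostate cancer", "pancreatic cancer", "other"]
_DISEASE_PROBS = [0.70, 0.15, 0.05, 0.05, 0.05]


class ConfigError(ValueError):
    """Invalid or infeasible generator configuration."""


@dataclass(frozen=True)
class PlantedAssociation:
    """A drug-event pair with known association strength and onset law."""

    drug: str
    pt: str
    target_ror: float
    weibull_alpha: float
    weibull_beta: float
    outcome_probs: dict | None = None


@dataclass
class GeneratorConfig:
    n_cases: int
    drugs: list  # (name, marginal exposure probability)
    pts: list  # (name, background event probability)
    planted: list = field(default_factory=list)
    outcome_probs: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS))
    missing_date_rate: float = 0.10
    multi_dose_rate: float = 0.10
    concomitant_rate: float = 0.10
    date_window: tuple = ("2018-07-01", "2021-12-31")
    seed: int = 0


def default_config(n_cases: int = 20_000, seed: int = 0) -> GeneratorConfig:
    """The reference study conditions used throughout the test-bench.

    One rare target drug (2% of cases) with one planted association of
    target ROR 5 against a PT with 2% background probability, Weibull onset
    delays (alpha = 50 d, beta = 1.5); a handful of common co-medication
    drugs supplying the background cells; background PT probabilities kept
    well below the level where a rare drug could reach the 10-case screen by
    chance.
    """
    drugs = [
        ("olaparib", 0.02),
        ("niraparib", 0.012),
        ("carboplatin", 0.25),
        ("paclitaxel", 0.22),
        ("bevacizumab", 0.18),
        ("gemcitabine", 0.15),
        ("doxorubicin", 0.12),
    ]
    pts = [
        ("anaemia", 0.020),
        ("nausea", 0.008),
        ("vomiting", 0.006),
        ("platelet count decreased", 0.006),
        ("neutrophil count decreased", 0.006),
        ("pyrexia", 0.006),
        ("diarrhoea", 0.006),
        ("fatigue", 0.005),
        ("decreased appetite", 0.005),
        ("rash", 0.005),
        ("thrombocytopenia", 0.005),
        ("interstitial lung disease", 0.004),
        ("malaise", 0.004),
        ("renal impairment", 0.004),
        ("ileus", 0.003),
    ]
    planted = [
        PlantedAssociation(
            drug="olaparib", pt="anaemia", target_ror=5.0,
            weibull_alpha=50.0, weibull_beta=1.5,
        )
    ]
    return GeneratorConfig(n_cases=n_cases, drugs=drugs, pts=pts, planted=planted, seed=seed)


def _tilted_probability(q: float, target_ror: float, s: float) -> float:
    """Event probability among suspect-exposed cases that makes the expected
    pair-unit ROR equal ``target_ror`` (s = suspect-exposure probability)."""
    denom = 1.0 - target_ror * s
    if denom <= 0:
        return float("inf")
    return target_ror * q * (1.0 - s) / denom


def _validate(cfg: GeneratorConfig) -> None:
    if cfg.n_cases <= 0:
        raise ConfigError("n_cases must be positive")
    drug_names = [d for d, _ in cfg.drugs]
    pt_names = [p for p, _ in cfg.pts]
    if len(set(drug_names)) != len(drug_names) or len(set(pt_names)) != len(pt_names):
        raise ConfigError("duplicate drug or pt names")
    for name, p in list(cfg.drugs) + list(cfg.pts):
        if not 0.0 < p < 1.0:
            raise ConfigError(f"probability for {name!r} must be in (0, 1), got {p}")
    total = sum(cfg.outcome_probs.get(c, 0.0) for c in OUTCOME_DRAW_ORDER)
    if abs(total - 1.0) > 1e-9:
        raise ConfigError("outcome_probs must sum to 1")
    for a in cfg.planted:
        if a.drug not in drug_names:
            raise ConfigError(f"planted association references undeclared drug {a.drug!r}")
        if a.pt not in pt_names:
            raise ConfigError(f"planted association references undeclared pt {a.pt!r}")
        if a.target_ror <= 0 or a.weibull_alpha <= 0 or a.weibull_beta <= 0:
            raise ConfigError("planted parameters must be positive")
        q = dict(cfg.pts)[a.pt]
        s = dict(cfg.drugs)[a.drug] * (1.0 - cfg.concomitant_rate)
        p1 = _tilted_probability(q, a.target_ror, s)
        if not 0.0 < p1 < 1.0:
            raise ConfigError(
                f"infeasible tilt for ({a.drug}, {a.pt}): required probability {p1}"
            )
        if a.outcome_probs is not None:
            s = sum(a.outcome_probs.get(c, 0.0) for c in OUTCOME_DRAW_ORDER)
            if abs(s - 1.0) > 1e-9:
                raise ConfigError("per-association outcome_probs must sum to 1")


def _format_dates(offsets: np.ndarray, origin: np.datetime64) -> np.ndarray:
    dates = origin + offsets.astype("timedelta64[D]")
    return np.datetime_as_string(dates, unit="D")


def _degrade_dates(iso: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Independently degrade a fraction of day-precision dates: half of the
    degraded ones drop to month precision, half go missing."""
    if rate <= 0 or iso.size == 0:
        return iso
    u = rng.random(iso.size)
    out = iso.astype(object)
    month_mask = u < rate / 2.0
    out[month_mask] = [s[:7] for s in out[month_mask]]
    out[(u >= rate / 2.0) & (u < rate)] = ""
    return out


def _draw_outcomes(
    u: np.ndarray, probs: dict, order=OUTCOME_DRAW_ORDER
) -> np.ndarray:
    cum = np.cumsum([probs.get(c, 0.0) for c in order])
    idx = np.searchsorted(cum, u, side="right")
    idx = np.clip(idx, 0, len(order) - 1)
    return np.array(order, dtype=object)[idx]


def generate(cfg: GeneratorConfig) -> tuple[Database, dict]:
    """Generate a four-table database plus a ground-truth ledger."""
    _validate(cfg)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases
    drug_names = [d for d, _ in cfg.drugs]
    drug_probs = np.array([p for _, p in cfg.drugs])
    pt_names = [p for p, _ in cfg.pts]
    pt_probs = np.array([q for _, q in cfg.pts])
    D, K = len(drug_names), len(pt_names)
    w0 = np.datetime64(cfg.date_window[0])
    w1 = np.datetime64(cfg.date_window[1])
    span = int((w1 - w0) / np.timedelta64(1, "D"))
    if span <= 0:
        raise ConfigError("empty date window")

    case_ids = np.array([f"C{i:07d}" for i in range(1, n + 1)])

    # --- demographics -----------------------------------------------------
    sex = rng.choice(["female", "male"], size=n, p=[0.85, 0.15])
    age_band = rng.choice(_AGE_BANDS, size=n, p=_AGE_PROBS)
    report_off = rng.integers(0, span + 1, size=n)
    report_dates = pd.DatetimeIndex(w0 + report_off.astype("timedelta64[D]"))
    report_period = (
        report_dates.year.astype(str) + "-Q" + ((report_dates.month - 1) // 3 + 1).astype(str)
    )

    # --- exposures and start dates ---------------------------------------
    expo = rng.random((n, D)) < drug_probs
    conc = rng.random((n, D)) < cfg.concomitant_rate
    suspect = expo & ~conc
    start_off = rng.integers(0, span + 1, size=(n, D))
    multi = (rng.random((n, D)) < cfg.multi_dose_rate) & expo
    second_gap = rng.integers(30, 200, size=(n, D))

    # --- events -----------------------------------------------------------
    prob = np.broadcast_to(pt_probs, (n, K)).copy()
    planted_idx = []
    for a in cfg.planted:
        j = drug_names.index(a.drug)
        k = pt_names.index(a.pt)
        s_j = drug_probs[j] * (1.0 - cfg.concomitant_rate)
        prob[suspect[:, j], k] = _tilted_probability(pt_probs[k], a.target_ror, s_j)
        planted_idx.append((a, j, k))
    events = rng.random((n, K)) < prob

    # --- onset offsets ----------------------------------------------------
    # anchor each case's background onsets to its earliest suspect start
    any_susp = suspect.any(axis=1)
    masked_starts = np.where(suspect, start_off, span + 1)
    anchor = masked_starts.min(axis=1)
    bg_delay = np.rint(rng.exponential(60.0, size=(n, K))).astype(np.int64)
    random_onset = rng.integers(0, span + 1, size=(n, K))
    onset_off = np.where(any_susp[:, None], anchor[:, None] + bg_delay, random_onset)
    for a, j, k in planted_idx:
        delay = np.rint(a.weibull_alpha * rng.weibull(a.weibull_beta, size=n)).astype(np.int64)
        mask = suspect[:, j] & events[:, k]
        onset_off[mask, k] = start_off[mask, j] + delay[mask]

    # --- outcomes ---------------------------------------------------------
    u_out = rng.random((n, K))
    outcome = _draw_outcomes(u_out, cfg.outcome_probs)
    for a, j, k in planted_idx:
        if a.outcome_probs is not None:
            mask = suspect[:, j] & events[:, k]
            outcome[mask, k] = _draw_outcomes(u_out[mask, k], a.outcome_probs)

    # --- DRUG table -------------------------------------------------------
    ei, ej = np.nonzero(expo)
    drug_start_iso = _format_dates(start_off[ei, ej], w0)
    drug_start_iso = _degrade_dates(drug_start_iso.astype(object), cfg.missing_date_rate, rng)
    duration = rng.integers(7, 400, size=ei.size)
    drug_end_iso = _format_dates(start_off[ei, ej] + duration, w0)
    drug_rows = pd.DataFrame(
        {
            "case_id": case_ids[ei],
            "drug_name": np.array(drug_names, dtype=object)[ej],
            "involvement": np.where(conc[ei, ej], "concomitant", "suspect"),
            "start_date": drug_start_iso,
            "end_date": drug_end_iso,
            "route": "oral",
        }
    )
    mi, mj = np.nonzero(multi)
    if mi.size:
        re_start = start_off[mi, mj] + second_gap[mi, mj]
        re_iso = _degrade_dates(
            _format_dates(re_start, w0).astype(object), cfg.missing_date_rate, rng
        )
        re_rows = pd.DataFrame(
            {
                "case_id": case_ids[mi],
                "drug_name": np.array(drug_names, dtype=object)[mj],
                "involvement": np.where(conc[mi, mj], "concomitant", "suspect"),
                "start_date": re_iso,
                "end_date": _format_dates(re_start + rng.integers(7, 400, size=mi.size), w0),
                "route": "oral",
            }
        )
        drug_rows = pd.concat([drug_rows, re_rows], ignore_index=True)
    drug_rows = drug_rows.sort_values(
        ["case_id", "drug_name", "start_date"], kind="mergesort"
    ).reset_index(drop=True)

    # --- REAC table -------------------------------------------------------
    ri, rk = np.nonzero(events)
    onset_iso = _format_dates(onset_off[ri, rk], w0).astype(object)
    onset_iso = _degrade_dates(onset_iso, cfg.missing_date_rate, rng)
    reac_rows = pd.DataFrame(
        {
            "case_id": case_ids[ri],
            "pt": np.array(pt_names, dtype=object)[rk],
            "onset_date": onset_iso,
            "outcome": outcome[ri, rk],
        }
    ).sort_values(["case_id", "pt"], kind="mergesort").reset_index(drop=True)

    # --- DEMO / HIST ------------------------------------------------------
    demo_rows = pd.DataFrame(
        {
            "case_id": case_ids,
            "sex": sex,
            "age_band": age_band,
            "report_period": report_period,
        }
    )
    hist_rows = pd.DataFrame(
        {
            "case_id": case_ids,
            "disease": rng.choice(_DISEASES, size=n, p=_DISEASE_PROBS),
        }
    )

    db = Database(
        demo=demo_rows.astype(str),
        drug=drug_rows.astype(str),
        reac=reac_rows.astype(str),
        hist=hist_rows.astype(str),
    )

    # --- ledger -----------------------------------------------------------
    # realized case-PT pair counts under the suspect-only pair unit
    M = suspect.astype(np.int64).T @ events.astype(np.int64)
    total_pairs = int(M.sum())
    pair_counts = {
        drug_names[j]: {
            pt_names[k]: int(M[j, k]) for k in range(K) if M[j, k] > 0
        }
        for j in range(D)
        if M[j].sum() > 0
    }
    planted_entries = []
    for a, j, k in planted_idx:
        cells = {
            "a": int(M[j, k]),
            "b": int(M[j].sum() - M[j, k]),
            "c": int(M[:, k].sum() - M[j, k]),
            "d": int(total_pairs - M[j].sum() - M[:, k].sum() + M[j, k]),
        }
        aa, bb, cc, dd = (cells[x] + (0.5 if min(cells.values()) == 0 else 0.0) for x in "abcd")
        planted_entries.append(
            {
                "drug": a.drug,
                "pt": a.pt,
                "target_ror": a.target_ror,
                "weibull_alpha": a.weibull_alpha,
                "weibull_beta": a.weibull_beta,
                "tilted_probability": _tilted_probability(
                    dict(cfg.pts)[a.pt], a.target_ror,
                    dict(cfg.drugs)[a.drug] * (1.0 - cfg.concomitant_rate),
                ),
                "cells": cells,
                "sample_or": (aa * dd) / (bb * cc) if bb * cc > 0 else None,
            }
        )
    ledger = {
        "seed": int(cfg.seed),
        "n_cases": int(n),
        "date_window": list(cfg.date_window),
        "totals": {
            "demo_rows": int(n),
            "drug_rows": int(len(drug_rows)),
            "reac_rows": int(len(reac_rows)),
            "hist_rows": int(n),
            "pairs_suspect": total_pairs,
            "pairs_all": int(expo.astype(np.int64).T.dot(events.astype(np.int64)).sum()),
        },
        "pair_counts": pair_counts,
        "planted": planted_entries,
    }
    return db, ledger


def write_database(
    db: Database, ledger: dict, outdir: str | Path, dialect: CsvDialect | None = None
) -> dict[str, Path]:
    """Write demo/drug/reac/hist CSVs plus ledger.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {t: outdir / f"{t}.csv" for t in ("demo", "drug", "reac", "hist")}
    write_tables(db, paths, dialect)
    ledger_path = outdir / "ledger.json"
    ledger_path.write_text(json.dumps(ledger, indent=2, sort_keys=True) + "\n")
    paths["ledger"] = ledger_path
    return paths


def table1_fixture() -> pd.DataFrame:
    """Published report-count/ROR table (see :mod:`pvsignal.published`)."""
    return signal_table()


def config_to_dict(cfg: GeneratorConfig) -> dict:
    out = dataclasses.asdict(cfg)
    out["planted"] = [dataclasses.asdict(a) for a in cfg.planted]
    return out


def config_from_dict(data: dict) -> GeneratorConfig:
    data = dict(data)
    data["drugs"] = [tuple(x) for x in data["drugs"]]
    data["pts"] = [tuple(x) for x in data["pts"]]
    data["planted"] = [PlantedAssociation(**a) for a in data.get("planted", [])]
    if "date_window" in data:
        data["date_window"] = tuple(data["date_window"])
    return GeneratorConfig(**data)
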