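"""End-to-end orchestration: ingest -> pairs -> signals -> TTO -> outcomes.

``run_pipeline`` sequences the whole analysis for a list of target drugs and
emits diff-able, deterministic TSV reports plus a ``run.json`` provenance
record (config echo, SHA-256 input hashes, per-stage counts, package
version).  Time-to-onset and outcome analyses are restricted to the PTs that
passed the signal screen, mirroring how signal-generating studies proceed.
Every pair examined for TTO appears exactly once in either the observations
or the exclusion log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .analysis_builder import build_pairs
from .disproportionality import detect_signals, format_signals
from .outcomes import outcomes_table, tabulate_outcomes
from .srs_io import CsvDialect, link_cases, read_tables

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    demo: str
    drug: str
    reac: str
    hist: str
    drugs: list = field(default_factory=list)  # target drugs; empty = all
    dialect: str | None = None
    min_cases: int = 10
    alpha_level: float = 0.05
    cap_days: float = 730.0
    start_rule: str = "earliest"
    suspect_only: bool = True
    outdir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if self.cap_days <= 0:
            raise ValueError("cap_days must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class PipelineResult:
    signals: pd.DataFrame
    tto: pd.DataFrame
    outcomes: pd.DataFrame
    exclusions: pd.DataFrame
    run_info: dict


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _round_cols(df: pd.DataFrame, spec: dict) -> pd.DataFrame:
    out = df.copy()
    for col, nd in spec.items():
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: round(v, nd) if isinstance(v, float) and pd.notna(v) else v
            )
    return out


def run_pipeline(cfg: RunConfig, write: bool = True) -> PipelineResult:
    """Run the full analysis; optionally write the report bundle to disk."""
    from .time_to_onset import tto_table  # local import avoids cycle at doc build

    dialect = CsvDialect.from_file(cfg.dialect) if cfg.dialect else CsvDialect()
    paths = {"demo": cfg.demo, "drug": cfg.drug, "reac": cfg.reac, "hist": cfg.hist}
    db = read_tables(paths, dialect)
    _, orphans = link_cases(db)
    pairs = build_pairs(db, suspect_only=cfg.suspect_only)
    targets = list(cfg.drugs) or sorted(pairs["drug_name"].unique())

    signal_frames, tto_frames, exc_frames, outcome_frames = [], [], [], []
    for drug in targets:
        signals = detect_signals(
            pairs, drug, min_cases=cfg.min_cases, alpha_level=cfg.alpha_level
        )
        signal_frames.append(signals)
        signal_pts = signals.loc[signals["is_signal"], "pt"].tolist()
        tto, exc = tto_table(
            pairs, drug, pts=signal_pts, cap_days=cfg.cap_days,
            start_rule=cfg.start_rule, alpha_level=cfg.alpha_level,
        )
        tto_frames.append(tto)
        exc_frames.append(exc)
        outcome_frames.append(outcomes_table(tabulate_outcomes(pairs, drug, signal_pts)))

    def _concat(frames, columns):
        frames = [f for f in frames if len(f)]
        if not frames:
            return pd.DataFrame(columns=columns)
        return pd.concat(frames, ignore_index=True)

    signals_all = _concat(signal_frames, ["drug", "pt"])
    tto_all = _concat(tto_frames, ["drug", "pt"])
    exclusions = _concat(exc_frames, ["case_id", "drug_name", "pt", "reason"])
    outcomes_all = _concat(outcome_frames, ["drug", "pt", "n"])

    run_info = {
        "package_version": __version__,
        "config": dataclasses.asdict(cfg),
        "input_sha256": {k: _sha256(v) for k, v in paths.items()},
        "counts": {
            "input_rows": db.row_counts(),
            "orphan_rows": orphans.counts,
            "pairs": int(len(pairs)),
            "target_drugs": targets,
            "signals": int(signals_all["is_signal"].sum()) if len(signals_all) else 0,
            "tto_observations": int(tto_all["n"].sum()) if len(tto_all) else 0,
            "tto_exclusions": int(len(exclusions)),
        },
    }

    result = PipelineResult(
        signals=signals_all, tto=tto_all, outcomes=outcomes_all,
        exclusions=exclusions, run_info=run_info,
    )
    if write:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        disp = format_signals(signals_all) if len(signals_all) else signals_all
        disp.to_csv(outdir / "signals.tsv", sep="\t", index=False, lineterminator="\n")
        _round_cols(
            tto_all,
            {"median": 1, "q1": 1, "q3": 1, "alpha": 2, "alpha_lo": 2, "alpha_hi": 2,
             "beta": 2, "beta_lo": 2, "beta_hi": 2},
        ).to_csv(outdir / "tto.tsv", sep="\t", index=False, lineterminator="\n")
        outcomes_all.to_csv(outdir / "outcomes.tsv", sep="\t", index=False, lineterminator="\n")
        exclusions.to_csv(outdir / "exclusions.tsv", sep="\t", index=False, lineterminator="\n")
        (outdir / "run.json").write_text(
            json.dumps(run_info, indent=2, sort_keys=True) + "\n"
        )
    return result
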