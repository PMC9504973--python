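"""Post-event outcome tabulation for the simulated signal PTs.

Outcome-bearing reports only (missing outcomes drop out of the
denominator), percentages half-up to one decimal -- the layout of a
published outcome table.  Writes results/synthetic_outcomes.tsv.
"""

from pathlib import Path

from pvsignal.analysis_builder import build_pairs
from pvsignal.disproportionality import detect_signals
from pvsignal.outcomes import outcomes_table, tabulate_outcomes
from pvsignal.srs_io import read_tables

ROOT = Path(__file__).resolve().parents[1] / "results"
DB = ROOT / "synthetic_db"
if not DB.exists():
    raise SystemExit("run analysis/02_simulate_database.py first")

db = read_tables({t: DB / f"{t}.csv" for t in ("demo", "drug", "reac", "hist")})
pairs = build_pairs(db)
signals = detect_signals(pairs, "olaparib")
signal_pts = signals.loc[signals.is_signal, "pt"].tolist()

summaries = tabulate_outcomes(pairs, "olaparib", signal_pts)
tab = outcomes_table(summaries)
tab.to_csv(ROOT / "synthetic_outcomes.tsv", sep="\t", index=False, lineterminator="\n")
print(tab.to_string(index=False))
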