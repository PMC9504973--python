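"""ROR signal screen on the simulated database.

Reads results/synthetic_db (run 02_simulate_database.py first), builds the
suspect-only case-PT pair table and screens every PT reported with the
target drug.  The planted (olaparib, anaemia) pair should be the only
signal clearing the 10-case screen.  Writes results/synthetic_signals.tsv.
"""

import json
from pathlib import Path

from pvsignal.analysis_builder import build_pairs
from pvsignal.disproportionality import detect_signals, format_signals
from pvsignal.srs_io import read_tables

ROOT = Path(__file__).resolve().parents[1] / "results"
DB = ROOT / "synthetic_db"
if not DB.exists():
    raise SystemExit("run analysis/02_simulate_database.py first")

db = read_tables({t: DB / f"{t}.csv" for t in ("demo", "drug", "reac", "hist")})
pairs = build_pairs(db)
signals = detect_signals(pairs, "olaparib", min_cases=10)
format_signals(signals).to_csv(
    ROOT / "synthetic_signals.tsv", sep="\t", index=False, lineterminator="\n"
)

flagged = signals[signals.is_signal]
ledger = json.loads((DB / "ledger.json").read_text())
print(f"pairs: {len(pairs)} (ledger: {ledger['totals']['pairs_suspect']})")
print(f"signals for olaparib: {list(flagged.pt)}")
print(flagged[["pt", "cases", "ror", "ci_low", "ci_high"]].round(2).to_string(index=False))
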