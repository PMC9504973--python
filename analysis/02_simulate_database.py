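"""Generate the reference synthetic JADER-schema database.

20,000 cases with one planted association -- (olaparib, anaemia), target
ROR 5, Weibull(alpha=50 d, beta=1.5) onset delays -- plus six common
co-medication drugs and fourteen background adverse events.  Writes the
four CSV tables and the ground-truth ledger to results/synthetic_db/.
"""

from pathlib import Path

from pvsignal.synthetic import default_config, generate, write_database

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic_db"

cfg = default_config(n_cases=20_000, seed=42)
db, ledger = generate(cfg)
write_database(db, ledger, OUT)

entry = ledger["planted"][0]
print(f"wrote {OUT} ({ledger['totals']})")
print(f"planted ({entry['drug']}, {entry['pt']}): target ROR {entry['target_ror']}, "
      f"realized cells {entry['cells']}, sample OR {entry['sample_or']:.2f}")
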