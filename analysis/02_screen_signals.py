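#!/usr/bin/env python
"""BCPNN signal screen over all (ICI drug, pituitary HLT) pairs.

Loads the synthetic extract written by 01_simulate.py, restricts to
suspect-drug mentions, computes the information component with 95%
credible bounds for each of the 24 pairs, and writes the screen table to
results/signal_screen.csv.  The planted ipilimumab association should be
the only pair whose IC025 clears the 1-bit signal threshold.
"""

import sys
from pathlib import Path

from srsignal import (
    TermMap,
    load_database,
    restrict_to_suspect,
    run_signal_screen,
    screen_to_frame,
)
from srsignal.simulate import ICI_DRUGS, PITUITARY_HLTS

RESULTS = Path(__file__).resolve().parents[1] / "results"
DB_DIR = RESULTS / "synthetic_db"


def load_study_db():
    if not (DB_DIR / "demo.csv").exists():
        sys.exit("no database found: run analysis/01_simulate.py first")
    db = load_database({k: DB_DIR / f"{k}.csv"
                        for k in ("demo", "drug", "reac", "hist")})
    return restrict_to_suspect(db), TermMap.from_csv(DB_DIR / "term_map.csv")


def main() -> None:
    db, term_map = load_study_db()
    results = run_signal_screen(db, list(ICI_DRUGS), list(PITUITARY_HLTS), term_map)
    frame = screen_to_frame(results)
    out = RESULTS / "signal_screen.csv"
    frame.to_csv(out, index=False)

    flagged = frame[frame.classification == "signal"]
    print(f"screened {len(frame)} (drug, HLT) pairs over {db.n_reports} reports")
    print(f"signals detected: {len(flagged)}")
    with_counts = frame[frame.n11 > 0].copy()
    for col in ("expected", "ic", "ic025", "ic975"):
        with_counts[col] = with_counts[col].round(2)
    print(with_counts.to_string(index=False))
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
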