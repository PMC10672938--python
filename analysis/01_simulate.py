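#!/usr/bin/env python
"""Generate the study database: a synthetic JADER-shaped extract.

Draws a 20,000-report spontaneous-report database containing the six
immune checkpoint inhibitors, four pituitary HLT event groups and a
background of common drugs and events, with one planted association —
ipilimumab x anterior pituitary hypofunction at reporting-rate ratio 40,
a 2x female excess and Weibull(120, 1.6) onset latencies — and writes the
four JADER-layout tables plus the PT->HLT term map to results/synthetic_db/.
"""

import json
from pathlib import Path

from srsignal import make_paper_fixture, write_tables

SEED = 1963
N_REPORTS = 20_000
OUTDIR = Path(__file__).resolve().parents[1] / "results" / "synthetic_db"


def main() -> None:
    db, term_map, config = make_paper_fixture(n_reports=N_REPORTS, seed=SEED)
    paths = write_tables(db, term_map, OUTDIR)
    (OUTDIR / "generator_config.json").write_text(
        config.model_dump_json(indent=2) + "\n")

    print(f"wrote {len(paths)} files to {OUTDIR}")
    print(db.summary().to_string(index=False))
    planted = config.associations[0]
    print(f"planted: {planted.drug} x {planted.hlt} "
          f"(rate ratio {planted.rate_ratio:g}, "
          f"women multiplier {planted.women_multiplier:g}, "
          f"onset Weibull(alpha={planted.onset_alpha:g}, "
          f"beta={planted.onset_beta:g}))")


if __name__ == "__main__":
    main()
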