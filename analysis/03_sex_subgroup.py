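#!/usr/bin/env python
"""Women-vs-men IC-delta contrast for every screened pair.

The planted association carries a 2x female excess on the reporting-rate
ratio.  Two regimes are shown.  In the miniature extract the planted drug
reaches 5% of all reports, so the association itself dominates both
strata's event margins and the contrast is attenuated toward 0 — the
statistic compares per-sex observed-to-expected ratios, and both expected
counts absorb a high-margin association.  A second experiment at
realistic rare exposure (0.5% of reports) recovers the excess as an
IC-delta near log2(2) = 1 bit.  Writes results/sex_subgroup.csv.
"""

import importlib.util
import sys
from pathlib import Path

from srsignal import (
    build_sex_tables,
    flag_event_group,
    ic_delta,
    restrict_to_suspect,
    run_subgroup_screen,
    subgroup_to_frame,
)
from srsignal.simulate import (
    Association,
    GeneratorConfig,
    ICI_DRUGS,
    PITUITARY_HLTS,
    PtSpec,
    generate,
)

_spec = importlib.util.spec_from_file_location(
    "screen_step", Path(__file__).with_name("02_screen_signals.py"))
screen_step = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(screen_step)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    db, term_map = screen_step.load_study_db()
    results = run_subgroup_screen(db, list(ICI_DRUGS), list(PITUITARY_HLTS),
                                  term_map)
    frame = subgroup_to_frame(results)
    out = RESULTS / "sex_subgroup.csv"
    frame.to_csv(out, index=False)

    shown = frame[frame.o_women + frame.o_men > 0].copy()
    for col in ("ic_women", "ic_women025", "ic_men", "ic_delta", "ic_delta025",
                "ic_delta975"):
        shown[col] = shown[col].round(2)
    print(shown.to_string(index=False))
    planted = frame[(frame.drug == "ipilimumab")
                    & (frame.hlt == "anterior pituitary hypofunction")].iloc[0]
    print(f"planted pair IC-delta = {planted.ic_delta:.2f} bits: the 2x female "
          "excess is masked because the planted exposure margin (5% of reports) "
          "contaminates both strata's expected counts")
    print(f"table -> {out}")

    # rare-exposure regime: the contrast statistic recovers the planted excess
    config = GeneratorConfig(
        n_reports=100_000,
        drug_catalog={"target": 0.005},
        event_catalog=[PtSpec(pt="pt_a", hlt="hlt_t", prob=0.08)],
        associations=[Association(drug="target", hlt="hlt_t", rate_ratio=4.0,
                                  women_multiplier=2.0)],
        seed=1963,
    )
    db2, _ = generate(config)
    db2 = restrict_to_suspect(db2)
    tables = build_sex_tables(db2, "target",
                              flag_event_group(db2, config.term_map(), "hlt_t"))
    res = ic_delta(tables, "target", "hlt_t")
    print(f"rare-exposure experiment (n=100,000, exposure 0.5%): IC-delta = "
          f"{res.ic_delta:.2f} bits ({res.ic_delta025:.2f}-{res.ic_delta975:.2f}) "
          f"for a planted 2x excess (log2 2 = 1.00); "
          f"women signal: {res.women_signal}")


if __name__ == "__main__":
    main()
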