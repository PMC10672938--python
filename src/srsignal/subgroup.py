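"""Women-vs-men subgroup disproportionality: the IC-delta contrast.

The subgroup contrast asks whether a drug–event pair is reported more
disproportionately in women than in men.  Each stratum gets its own
observed-to-expected ratio computed entirely within its own margins,

    OE_women = O_women / E_women,   E_women = Nw1+ · Nw+1 / Nw++
    OE_men   = O_men   / E_men,     E_men   = Nm1+ · Nm+1 / Nm++

and the contrast shrinks their ratio the same way the IC shrinks the plain
observed-to-expected ratio:

    E*       = E_women · OE_men          (women's expected count if women
                                          had the men's OE ratio)
    IC_delta = log2( (O_women + 0.5) / (E* + 0.5) ).

A *women signal* additionally requires all three of: IC_delta025 > 0,
O_women > 2, and the women-stratum IC025 > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bcpnn import IcResult, SignalThresholds, credible_interval, information_component
from .contingency import SexStratifiedTable, build_sex_tables
from .report_store import ReportDatabase, TermMap, flag_event_group

__all__ = [
    "IcDeltaResult",
    "ic_delta",
    "ic_delta_from_counts",
    "ic_delta_interval",
    "women_signal",
    "run_subgroup_screen",
    "subgroup_to_frame",
]


@dataclass(frozen=True)
class IcDeltaResult:
    drug: str
    event_group: str
    o_women: int
    e_women: float
    o_men: int
    e_men: float
    oe_women: float
    oe_men: float
    e_star: float
    ic_delta: float
    ic_delta025: float
    ic_delta975: float
    ic_women: float
    ic_women025: float
    women_signal: bool
    computable: bool = True


def ic_delta_interval(
    o_women: int,
    e_star: float,
    level: float = 0.95,
    method: str = "closed_form",
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Credible bounds for IC_delta: the IC interval machinery applied to (O_women, E*)."""
    return credible_interval(o_women, e_star, level, method=method, rng=rng)


def ic_delta_from_counts(
    o_women: int,
    e_women: float,
    o_men: int,
    e_men: float,
    drug: str = "",
    event_group: str = "",
    level: float = 0.95,
    method: str = "closed_form",
    rng: np.random.Generator | int | None = None,
) -> IcDeltaResult:
    """IC-delta from per-sex observed and expected counts.

    This is the entry point for worked examples where the per-sex expected
    counts are recovered from printed (O, IC) pairs rather than from raw
    tables.  ``o_men = 0`` or ``e_men <= 0`` makes OE_men degenerate: the
    result is flagged not-computable instead of silently zero.
    """
    if e_women <= 0 or e_men <= 0 or o_men == 0:
        nan = float("nan")
        return IcDeltaResult(drug, event_group, o_women, max(e_women, 0.0), o_men,
                             max(e_men, 0.0), nan, nan, nan, nan, nan, nan, nan, nan,
                             women_signal=False, computable=False)
    oe_women = o_women / e_women
    oe_men = o_men / e_men
    e_star = e_women * oe_men
    icd = math.log2((o_women + 0.5) / (e_star + 0.5))
    lo, hi = ic_delta_interval(o_women, e_star, level, method=method, rng=rng)
    ic_women = math.log2((o_women + 0.5) / (e_women + 0.5))
    icw_lo, _ = credible_interval(o_women, e_women, level, method=method, rng=rng)
    return IcDeltaResult(
        drug, event_group, o_women, e_women, o_men, e_men, oe_women, oe_men,
        e_star, icd, lo, hi, ic_women, icw_lo,
        women_signal=(lo > 0.0 and o_women > 2 and icw_lo > 0.0),
    )


def ic_delta(
    sex_tables: SexStratifiedTable,
    drug: str = "",
    event_group: str = "",
    level: float = 0.95,
    method: str = "closed_form",
    rng: np.random.Generator | int | None = None,
) -> IcDeltaResult:
    """IC-delta for one (drug, event-group) pair from its sex-stratified tables."""
    for stratum in (sex_tables.women, sex_tables.men):
        if stratum.nplusplus == 0:
            raise ValueError("both sex strata must contain reports")
    o_women, e_women, _ = information_component(sex_tables.women)
    o_men, e_men, _ = information_component(sex_tables.men)
    return ic_delta_from_counts(o_women, e_women, o_men, e_men,
                                drug=drug, event_group=event_group,
                                level=level, method=method, rng=rng)


def women_signal(delta: IcDeltaResult, women_ic: IcResult) -> bool:
    """Three-part women-signal rule: IC_delta025 > 0, O_women > 2, women IC025 > 0.

    ``women_ic`` must be the IC result computed on the women stratum for the
    same (drug, event-group) pair.
    """
    if (women_ic.drug, women_ic.event_group) != (delta.drug, delta.event_group):
        raise ValueError(
            f"pair mismatch: delta is for {(delta.drug, delta.event_group)}, "
            f"IC is for {(women_ic.drug, women_ic.event_group)}"
        )
    if not delta.computable:
        return False
    return bool(delta.ic_delta025 > 0.0 and delta.o_women > 2 and women_ic.ic025 > 0.0)


def run_subgroup_screen(
    db: ReportDatabase,
    drugs: Sequence[str],
    hlt_names: Sequence[str],
    term_map: TermMap,
    level: float = 0.95,
    method: str = "closed_form",
    rng: np.random.Generator | int | None = None,
) -> list[IcDeltaResult]:
    """One IcDeltaResult per (drug, HLT) pair in configured order."""
    rng = rng if isinstance(rng, np.random.Generator) or rng is None \
        else np.random.default_rng(rng)
    out = []
    flags = {hlt: flag_event_group(db, term_map, hlt) for hlt in hlt_names}
    for drug in drugs:
        for hlt in hlt_names:
            tables = build_sex_tables(db, drug, flags[hlt])
            try:
                res = ic_delta(tables, drug, hlt, level, method=method, rng=rng)
            except ValueError:
                nan = float("nan")
                res = IcDeltaResult(drug, hlt, tables.women.n11, nan, tables.men.n11,
                                    nan, nan, nan, nan, nan, nan, nan, nan, nan,
                                    women_signal=False, computable=False)
            out.append(res)
    return out


def subgroup_to_frame(results: Iterable[IcDeltaResult]) -> pd.DataFrame:
    def _ic_men(r: IcDeltaResult) -> float:
        if not r.computable or not (r.e_men > 0):
            return float("nan")
        return math.log2((r.o_men + 0.5) / (r.e_men + 0.5))

    return pd.DataFrame(
        [
            {
                "drug": r.drug, "hlt": r.event_group,
                "o_women": r.o_women, "ic_women": r.ic_women,
                "ic_women025": r.ic_women025, "o_men": r.o_men,
                "ic_men": _ic_men(r),
                "ic_delta": r.ic_delta, "ic_delta025": r.ic_delta025,
                "ic_delta975": r.ic_delta975, "women_signal": r.women_signal,
            }
            for r in results
        ],
        columns=["drug", "hlt", "o_women", "ic_women", "ic_women025", "o_men",
                 "ic_men", "ic_delta", "ic_delta025", "ic_delta975", "women_signal"],
    )
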