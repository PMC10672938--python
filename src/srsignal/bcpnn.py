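"""BCPNN information-component disproportionality statistics.

The information component (IC) is the Bayesian confidence propagation
neural network signal score used by the WHO Uppsala Monitoring Centre: a
shrunk log2 observed-to-expected reporting ratio,

    E  = N1+ · N+1 / N++
    IC = log2( (O + 0.5) / (E + 0.5) ),   O = N11.

The +0.5 shrinkage pulls small-count pairs toward IC = 0, so the statistic
is defined even at O = 0.  A pair is a *signal* when the lower bound of the
95% credible interval (IC025) exceeds the signal threshold (default 1 bit),
and an *inverse signal* when the upper bound (IC975) falls below the
inverse threshold (default 0).

Two interval methods are provided:

``closed_form`` (default)
    The O-dependent quantile approximation to the IC posterior,
    IC025 = IC − 3.3(O+0.5)^(−1/2) − 2.4(O+0.5)^(−1) and
    IC975 = IC + 2.4(O+0.5)^(−1/2) − 0.5(O+0.5)^(−1).
    Valid for the 95% level only.

``monte_carlo``
    Empirical quantiles of log2 of the shrunk observed-to-expected ratio
    under a Gamma(O + 0.5, 1) posterior scaled by 1/(E + 0.5).  Conditions
    on the expected count, so it is slightly narrower than the closed form
    at moderate O (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contingency import ContingencyTable, build_2x2
from .report_store import ReportDatabase, TermMap, flag_event_group

__all__ = [
    "SignalThresholds",
    "IcResult",
    "information_component",
    "expected_from_ic",
    "credible_interval",
    "classify",
    "run_signal_screen",
    "screen_to_frame",
]

CLASSIFICATIONS = ("signal", "inverse", "none", "not_available")


@dataclass(frozen=True)
class SignalThresholds:
    """Decision thresholds for the IC credible interval.

    ``signal_lower``: IC025 must exceed this for a signal (default 1 bit).
    ``inverse_upper``: IC975 must fall below this for an inverse signal
    (default 0).  ``credible_level`` is the interval mass (default 0.95).
    """

    signal_lower: float = 1.0
    inverse_upper: float = 0.0
    credible_level: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.credible_level < 1.0):
            raise ValueError("credible_level must lie in (0, 1)")
        if self.signal_lower <= self.inverse_upper:
            raise ValueError("signal_lower must exceed inverse_upper")


@dataclass(frozen=True)
class IcResult:
    drug: str
    event_group: str
    observed_o: int
    expected_e: float
    ic: float
    ic025: float
    ic975: float
    classification: str


def information_component(table: ContingencyTable) -> tuple[int, float, float]:
    """Observed count, expected count under independence, and the shrunk IC."""
    if table.nplusplus == 0:
        raise ValueError("cannot compute an information component on an empty database")
    observed = table.n11
    expected = table.n1plus * table.nplus1 / table.nplusplus
    ic = math.log2((observed + 0.5) / (expected + 0.5))
    return observed, expected, ic


def expected_from_ic(observed_o: int, ic: float) -> float:
    """Invert the shrunk IC: the expected count implied by a printed (O, IC) pair."""
    return (observed_o + 0.5) / 2.0 ** ic - 0.5


def credible_interval(
    observed_o: int,
    expected_e: float,
    level: float = 0.95,
    method: str = "closed_form",
    n_draws: int = 1_000_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Credible bounds for the IC of a pair with ``observed_o`` / ``expected_e``.

    The closed form is a 95%-only approximation; ask for another level and
    you must use the Monte-Carlo method.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("credible level must lie in (0, 1)")
    if observed_o < 0 or expected_e <= 0:
        raise ValueError("need observed_o >= 0 and expected_e > 0")
    shrunk_o = observed_o + 0.5
    ic = math.log2(shrunk_o / (expected_e + 0.5))
    if method == "closed_form":
        if abs(level - 0.95) > 1e-9:
            raise ValueError("closed_form interval is calibrated for level=0.95 only")
        lo = ic - 3.3 * shrunk_o ** -0.5 - 2.4 / shrunk_o
        hi = ic + 2.4 * shrunk_o ** -0.5 - 0.5 / shrunk_o
        return lo, hi
    if method == "monte_carlo":
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        draws = stats.gamma.rvs(a=shrunk_o, scale=1.0, size=n_draws, random_state=rng)
        post = np.log2(draws / (expected_e + 0.5))
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(post, [alpha, 1.0 - alpha])
        return float(lo), float(hi)
    raise ValueError(f"unknown interval method {method!r}")


def classify(result: IcResult, thresholds: SignalThresholds = SignalThresholds()) -> str:
    """Signal taxonomy for one pair: signal / inverse / none / not_available.

    ``not_available`` mirrors the convention of reporting "NA" for pairs
    with zero co-reports.  Thresholds compare against unrounded bounds.
    """
    if result.observed_o == 0:
        return "not_available"
    if result.ic025 > thresholds.signal_lower:
        return "signal"
    if result.ic975 < thresholds.inverse_upper:
        return "inverse"
    return "none"


def _make_result(
    drug: str,
    hlt: str,
    table: ContingencyTable,
    thresholds: SignalThresholds,
    method: str,
    rng: np.random.Generator | None,
) -> IcResult:
    observed, expected, ic = information_component(table)
    if expected > 0:
        lo, hi = credible_interval(observed, expected, thresholds.credible_level,
                                   method=method, rng=rng)
    else:  # drug or event absent: no interval is defined
        lo = hi = float("nan")
    partial = IcResult(drug, hlt, observed, expected, ic, lo, hi, "none")
    return IcResult(drug, hlt, observed, expected, ic, lo, hi,
                    classify(partial, thresholds))


def run_signal_screen(
    db: ReportDatabase,
    drugs: Sequence[str],
    hlt_names: Sequence[str],
    term_map: TermMap,
    thresholds: SignalThresholds = SignalThresholds(),
    method: str = "closed_form",
    rng: np.random.Generator | int | None = None,
) -> list[IcResult]:
    """One IcResult per (drug, HLT) pair, in the configured drug-major order."""
    rng = rng if isinstance(rng, np.random.Generator) or rng is None \
        else np.random.default_rng(rng)
    results = []
    flags = {hlt: flag_event_group(db, term_map, hlt) for hlt in hlt_names}
    for drug in drugs:
        for hlt in hlt_names:
            table = build_2x2(db, drug, flags[hlt])
            results.append(_make_result(drug, hlt, table, thresholds, method, rng))
    return results


def screen_to_frame(results: Iterable[IcResult]) -> pd.DataFrame:
    """Long-format screen output with a fixed column order."""
    return pd.DataFrame(
        [
            {
                "drug": r.drug, "hlt": r.event_group, "n11": r.observed_o,
                "expected": r.expected_e, "ic": r.ic, "ic025": r.ic025,
                "ic975": r.ic975, "classification": r.classification,
            }
            for r in results
        ],
        columns=["drug", "hlt", "n11", "expected", "ic", "ic025", "ic975",
                 "classification"],
    )
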