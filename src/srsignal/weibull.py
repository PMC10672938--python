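"""Weibull time-to-onset analysis and onset-pattern classification.

Spontaneous reports carry an administration start date and an event onset
date; their difference (inclusive day counting, so same-day onset is day 1)
is the time-to-onset latency T.  Latencies are modelled with a
two-parameter Weibull distribution — hazard

    lambda(T) = (beta / alpha) * (T / alpha)**(beta - 1)

with scale alpha (days) and shape beta.  The shape parameter carries the
onset pattern: beta > 1 means an increasing hazard (*wear-out failure*,
onset rate grows with time on drug), beta = 1 a constant hazard (*random
failure*), beta < 1 a decreasing hazard (*early failure*).  Classification
is interval-based: a pattern is asserted only when the 95% CI of beta lies
wholly on one side of 1; otherwise it is indeterminate.

Fitting is uncensored maximum likelihood (spontaneous reports contain only
realized events), optimized over (log alpha, log beta) with Wald confidence
bounds from the observed information on the log scale, exponentiated back —
so the bounds are always positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .report_store import ReportDatabase, TermMap, normalize_drug_name

__all__ = [
    "TtoSample",
    "WeibullFit",
    "DegenerateSampleError",
    "extract_tto",
    "fit_weibull",
    "classify_pattern",
    "weibull_quantile",
    "tto_to_frame",
]

PATTERNS = ("early_failure", "random_failure", "wear_out", "indeterminate",
            "not_available")


class DegenerateSampleError(ValueError):
    """The latency sample has no spread; a Weibull fit would diverge."""


@dataclass(frozen=True)
class TtoSample:
    """Time-to-onset latencies (days, all >= 1) for one (drug, event-group) pair."""

    drug: str
    event_group: str
    days: tuple
    n_excluded_missing: int
    n_excluded_nonpositive: int

    @property
    def n_used(self) -> int:
        return len(self.days)


@dataclass(frozen=True)
class WeibullFit:
    drug: str
    event_group: str
    n_used: int
    alpha: float
    beta: float
    alpha_ci: tuple
    beta_ci: tuple
    log_likelihood: float
    pattern: str
    gamma_loc: float = 0.0  # location fixed: two-parameter model

    @classmethod
    def unavailable(cls, drug: str, event_group: str, n_used: int) -> "WeibullFit":
        nan = float("nan")
        return cls(drug, event_group, n_used, nan, nan, (nan, nan), (nan, nan),
                   nan, "not_available")


def extract_tto(db: ReportDatabase, drug: str, term_map: TermMap,
                hlt_name: str) -> TtoSample:
    """Latency sample for cases exposed to ``drug`` that reported the HLT.

    For each such case, latency = (earliest onset date among the case's
    events in the HLT) − (earliest administration start among the case's
    suspect mentions of the drug) + 1 day, the +1 making same-day onset
    representable on Weibull support.  Cases with either date entirely
    missing are tallied in ``n_excluded_missing``; onsets strictly before
    the first administration are data errors tallied in
    ``n_excluded_nonpositive``.
    """
    name = normalize_drug_name(drug, db.drug_synonyms)
    mentions = db.drugs[
        (db.drugs["generic_name"] == name) & (db.drugs["involvement"] == "suspect")
    ]
    starts = mentions.dropna(subset=["admin_start_date"]) \
        .groupby("case_id")["admin_start_date"].min()
    exposed = set(mentions["case_id"])

    pts = term_map.pts_in(hlt_name)
    if not pts:
        raise KeyError(f"HLT {hlt_name!r} does not occur in the supplied term map")
    hits = db.events[db.events["pt_name"].isin(pts)]
    onsets = hits.dropna(subset=["onset_date"]).groupby("case_id")["onset_date"].min()
    flagged = set(hits["case_id"])

    days: list[int] = []
    n_missing = 0
    n_nonpositive = 0
    for case_id in sorted(exposed & flagged):
        if case_id not in starts.index or case_id not in onsets.index:
            n_missing += 1
            continue
        lag = (onsets[case_id] - starts[case_id]).days + 1
        if lag <= 0:
            n_nonpositive += 1
        else:
            days.append(int(lag))
    return TtoSample(drug, hlt_name, tuple(days), n_missing, n_nonpositive)


def _neg_loglik(log_params: np.ndarray, t: np.ndarray) -> float:
    log_alpha, log_beta = log_params
    alpha, beta = math.exp(log_alpha), math.exp(log_beta)
    z = t / alpha
    return -float(np.sum(math.log(beta / alpha) + special.xlogy(beta - 1.0, z) - z ** beta))


def _observed_information(log_params: np.ndarray, t: np.ndarray,
                          step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of the negative log-likelihood on the log scale."""
    n = len(log_params)
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            pp = log_params.copy(); pp[i] += step; pp[j] += step
            pm = log_params.copy(); pm[i] += step; pm[j] -= step
            mp = log_params.copy(); mp[i] -= step; mp[j] += step
            mm = log_params.copy(); mm[i] -= step; mm[j] -= step
            hess[i, j] = (_neg_loglik(pp, t) - _neg_loglik(pm, t)
                          - _neg_loglik(mp, t) + _neg_loglik(mm, t)) / (4 * step * step)
    return hess


def fit_weibull(sample: TtoSample | Sequence[int], min_n: int = 5,
                level: float = 0.95) -> WeibullFit:
    """Maximum-likelihood two-parameter Weibull fit of a latency sample.

    Samples smaller than ``min_n`` yield a ``not_available`` fit (no
    parameters are reported for pairs too sparse to estimate).  A sample
    with zero spread is refused with :class:`DegenerateSampleError`.
    """
    if isinstance(sample, TtoSample):
        drug, hlt, days = sample.drug, sample.event_group, np.asarray(sample.days, float)
    else:
        drug, hlt, days = "", "", np.asarray(sample, float)
    if np.any(days <= 0):
        raise ValueError("latencies must be positive days")
    if len(days) < min_n:
        return WeibullFit.unavailable(drug, hlt, len(days))
    if np.ptp(days) == 0:
        raise DegenerateSampleError(
            f"all {len(days)} latencies equal {days[0]:g} days; "
            "the Weibull shape is unbounded on a zero-spread sample"
        )

    # moment-flavoured start: log-scale regression of the Weibull CV relation
    log_t = np.log(days)
    beta0 = max(0.1, 1.2 / max(np.std(log_t), 1e-6))
    alpha0 = float(np.exp(np.mean(log_t) + 0.5772 / beta0))
    x0 = np.log([alpha0, beta0])
    res = optimize.minimize(_neg_loglik, x0, args=(days,), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    res = optimize.minimize(_neg_loglik, res.x, args=(days,), method="BFGS")
    log_alpha, log_beta = res.x
    alpha, beta = math.exp(log_alpha), math.exp(log_beta)

    info = _observed_information(res.x, days)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    from scipy.stats import norm
    z = norm.ppf(0.5 + level / 2.0)
    alpha_ci = (math.exp(log_alpha - z * se[0]), math.exp(log_alpha + z * se[0]))
    beta_ci = (math.exp(log_beta - z * se[1]), math.exp(log_beta + z * se[1]))

    fit = WeibullFit(drug, hlt, len(days), alpha, beta, alpha_ci, beta_ci,
                     -res.fun, "indeterminate")
    return WeibullFit(drug, hlt, len(days), alpha, beta, alpha_ci, beta_ci,
                      -res.fun, classify_pattern(fit))


def classify_pattern(fit: WeibullFit) -> str:
    """Onset pattern from the shape-parameter CI: wear_out / early_failure / indeterminate."""
    if fit.pattern == "not_available" or not np.isfinite(fit.beta):
        return "not_available"
    lo, hi = fit.beta_ci
    if lo > 1.0:
        return "wear_out"
    if hi < 1.0:
        return "early_failure"
    return "indeterminate"


def weibull_quantile(fit: WeibullFit, p: float) -> float:
    """Latency (days) by which a fraction ``p`` of onsets has occurred.

    T_p = alpha * (-ln(1-p))**(1/beta); at T = alpha the cumulative onset
    fraction is 1 - 1/e ≈ 63.2%.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly between 0 and 1")
    return fit.alpha * (-math.log1p(-p)) ** (1.0 / fit.beta)


def tto_to_frame(fits: Sequence[WeibullFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": f.drug, "hlt": f.event_group, "n_used": f.n_used,
                "alpha": f.alpha, "alpha_low": f.alpha_ci[0],
                "alpha_high": f.alpha_ci[1], "beta": f.beta,
                "beta_low": f.beta_ci[0], "beta_high": f.beta_ci[1],
                "pattern": f.pattern,
            }
            for f in fits
        ],
        columns=["drug", "hlt", "n_used", "alpha", "alpha_low", "alpha_high",
                 "beta", "beta_low", "beta_high", "pattern"],
    )
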