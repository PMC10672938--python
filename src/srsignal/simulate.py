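"""Synthetic JADER-shaped spontaneous-report databases with known ground truth.

Real spontaneous-report extracts cannot be redistributed, so every stage of
the pipeline is exercised against generated databases whose reporting
structure is known exactly.  The generative model is deliberately the
independence baseline that disproportionality statistics assume: per case,

* sex is women/men with a configurable split, a fraction reported unknown;
* each drug exposure is an independent Bernoulli draw on its margin;
* each preferred-term event is drawn with probability
  margin × rate-ratio (if the case is exposed to an associated drug whose
  HLT contains the PT) × women-multiplier (if additionally sex = women),
  clamped at 1 with a logged warning;
* events attributable to an association get an onset date equal to the
  drug's administration start plus a Weibull(alpha, beta) latency rounded
  up to whole days (so latencies are >= 1); background events get onset
  dates uniform over the reporting window;
* administration-start and onset dates are independently knocked out at a
  configurable missingness rate, emulating the incomplete dating of real
  reports.

Identical seeds give byte-identical databases.  Confounding, duplicate
case versions and launch-period reporting waves are intentionally absent:
under the null the generator is exactly null, so false-positive behaviour
is testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .report_store import ReportDatabase, TermMap

logger = logging.getLogger(__name__)

__all__ = ["Association", "PtSpec", "GeneratorConfig", "GroundTruth",
           "generate", "make_paper_fixture", "write_tables"]


class Association(BaseModel):
    """A planted drug–event-group dependence with optional female excess."""

    drug: str
    hlt: str
    rate_ratio: float = Field(gt=0)
    women_multiplier: float = Field(default=1.0, gt=0)
    onset_alpha: float = Field(default=120.0, gt=0)  # days
    onset_beta: float = Field(default=1.6, gt=0)


class PtSpec(BaseModel):
    """One preferred term: its HLT parent and marginal reporting probability."""

    pt: str
    hlt: str
    prob: float = Field(ge=0.0, le=1.0)


class GeneratorConfig(BaseModel):
    n_reports: int = Field(gt=0)
    drug_catalog: dict[str, float]
    event_catalog: list[PtSpec]
    associations: list[Association] = Field(default_factory=list)
    p_women_given_known: float = Field(default=0.5, ge=0.0, le=1.0)
    missing_sex_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    missing_date_rate: float = Field(default=0.35, ge=0.0, le=1.0)
    concomitant_rate: float = Field(default=0.3, ge=0.0, le=1.0)
    window_start: str = "2004-01-01"
    window_end: str = "2019-12-31"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for name, p in self.drug_catalog.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"exposure probability of {name!r} outside [0, 1]")
        pts = [e.pt for e in self.event_catalog]
        if len(set(pts)) != len(pts):
            raise ValueError("duplicate PT in event catalog")
        hlts = {e.hlt for e in self.event_catalog}
        drugs = set(self.drug_catalog)
        for a in self.associations:
            if a.drug not in drugs:
                raise ValueError(f"association drug {a.drug!r} not in drug catalog")
            if a.hlt not in hlts:
                raise ValueError(f"association HLT {a.hlt!r} not in event catalog")
        return self

    def term_map(self) -> TermMap:
        return TermMap({e.pt: e.hlt for e in self.event_catalog})


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: the config plus realized counts for sanity checks."""

    config: GeneratorConfig
    exposure_counts: dict
    event_counts: dict
    n_prob_clamped: int


def generate(config: GeneratorConfig,
             seed: Optional[int] = None) -> tuple[ReportDatabase, GroundTruth]:
    """Draw one database from the generative model; ``seed`` overrides config.seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_reports
    drug_names = list(config.drug_catalog)
    drug_probs = np.array([config.drug_catalog[d] for d in drug_names])
    pt_names = [e.pt for e in config.event_catalog]
    pt_probs = np.array([e.prob for e in config.event_catalog])
    pt_index = {pt: j for j, pt in enumerate(pt_names)}
    hlt_pts = {}
    for e in config.event_catalog:
        hlt_pts.setdefault(e.hlt, []).append(pt_index[e.pt])

    case_ids = np.array([f"C{i:07d}" for i in range(n)])

    sex = np.where(rng.random(n) < config.p_women_given_known, "women", "men")
    sex = np.where(rng.random(n) < config.missing_sex_rate, "unknown", sex)
    is_woman = sex == "women"

    exposed = rng.random((n, len(drug_names))) < drug_probs  # (case, drug)

    window_start = np.datetime64(config.window_start)
    span = int((np.datetime64(config.window_end) - window_start)
               / np.timedelta64(1, "D")) + 1
    start_day = rng.integers(0, span, size=(n, len(drug_names)))
    start_date = window_start + start_day.astype("timedelta64[D]")

    # event probabilities: margin, boosted where an association applies
    probs = np.tile(pt_probs, (n, 1))
    for a in config.associations:
        rows = exposed[:, drug_names.index(a.drug)]
        cols = hlt_pts[a.hlt]
        for j in cols:
            probs[rows, j] *= a.rate_ratio
            probs[rows & is_woman, j] *= a.women_multiplier
    n_clamped = int((probs > 1.0).sum())
    if n_clamped:
        logger.warning("clamped %d event probabilities that exceeded 1", n_clamped)
        probs = np.clip(probs, 0.0, 1.0)
    occurs = rng.random((n, len(pt_names))) < probs  # (case, pt)

    # onset dates: background uniform; association-attributed = start + Weibull
    onset_day = rng.integers(0, span, size=(n, len(pt_names)))
    onset = window_start + onset_day.astype("timedelta64[D]")
    for a in config.associations:
        d = drug_names.index(a.drug)
        rows = exposed[:, d]
        latency = np.ceil(a.onset_alpha * rng.weibull(a.onset_beta, size=n)).astype(int)
        latency = np.maximum(latency, 1)
        for j in hlt_pts[a.hlt]:
            attributed = rows & occurs[:, j]
            onset[attributed, j] = (start_date[attributed, d]
                                    + latency[attributed].astype("timedelta64[D]"))

    cases = pd.DataFrame({"case_id": case_ids, "sex": sex, "report_quarter": ""})

    ci, di = np.nonzero(exposed)
    drug_start = pd.Series(start_date[ci, di])
    drug_start[rng.random(len(ci)) < config.missing_date_rate] = pd.NaT
    # an independent concomitant layer, removed by the suspect-drug restriction
    conc = rng.random((n, len(drug_names))) < config.concomitant_rate * drug_probs
    ci2, di2 = np.nonzero(conc)
    name_arr = np.array(drug_names, dtype=object)
    drugs = pd.DataFrame({
        "case_id": np.concatenate([case_ids[ci], case_ids[ci2]]),
        "generic_name": np.concatenate([name_arr[di], name_arr[di2]]),
        "involvement": np.concatenate([np.repeat("suspect", len(ci)),
                                       np.repeat("concomitant", len(ci2))]),
        "admin_start_date": pd.concat(
            [pd.to_datetime(drug_start),
             pd.Series(pd.NaT, index=range(len(ci2)), dtype="datetime64[ns]")],
            ignore_index=True),
    })

    ei, pj = np.nonzero(occurs)
    ev_onset = pd.Series(onset[ei, pj])
    ev_onset[rng.random(len(ei)) < config.missing_date_rate] = pd.NaT
    events = pd.DataFrame({
        "case_id": case_ids[ei],
        "pt_name": np.array(pt_names, dtype=object)[pj],
        "onset_date": pd.to_datetime(ev_onset),
        "outcome": "",
    })

    db = ReportDatabase(cases=cases, drugs=drugs, events=events).validate()
    truth = GroundTruth(
        config=config,
        exposure_counts={d: int(exposed[:, k].sum()) for k, d in enumerate(drug_names)},
        event_counts={p: int(occurs[:, k].sum()) for k, p in enumerate(pt_names)},
        n_prob_clamped=n_clamped,
    )
    return db, truth


# -- the miniature study fixture -------------------------------------------

ICI_DRUGS = ("ipilimumab", "nivolumab", "pembrolizumab", "atezolizumab",
             "avelumab", "durvalumab")
PITUITARY_HLTS = ("anterior pituitary hypofunction",
                  "anterior pituitary hyperfunction",
                  "posterior pituitary disorder",
                  "pituitary neoplasm")


def make_paper_fixture(n_reports: int = 2000,
                       seed: int = 1963) -> tuple[ReportDatabase, TermMap, GeneratorConfig]:
    """A deterministic miniature study database used throughout the test suite.

    Six checkpoint-inhibitor drug names, four pituitary HLT groups with a
    few synthetic PTs each, a background of common drugs and events, and
    one planted association — ipilimumab × anterior pituitary hypofunction,
    reporting-rate ratio 40 with a 2× female excess and Weibull(120, 1.6)
    onsets — that the screen must recover as a signal.
    """
    config = GeneratorConfig(
        n_reports=n_reports,
        drug_catalog={
            "ipilimumab": 0.05, "nivolumab": 0.06, "pembrolizumab": 0.05,
            "atezolizumab": 0.03, "avelumab": 0.01, "durvalumab": 0.01,
            "cisplatin": 0.20, "carboplatin": 0.15, "paclitaxel": 0.12,
            "levothyroxine": 0.08, "metformin": 0.10, "amlodipine": 0.10,
        },
        event_catalog=[
            PtSpec(pt="hypopituitarism", hlt=PITUITARY_HLTS[0], prob=0.002),
            PtSpec(pt="secondary adrenocortical insufficiency", hlt=PITUITARY_HLTS[0], prob=0.002),
            PtSpec(pt="hypophysitis", hlt=PITUITARY_HLTS[0], prob=0.001),
            PtSpec(pt="hyperprolactinaemia", hlt=PITUITARY_HLTS[1], prob=0.001),
            PtSpec(pt="diabetes insipidus", hlt=PITUITARY_HLTS[2], prob=0.002),
            PtSpec(pt="inappropriate antidiuresis", hlt=PITUITARY_HLTS[2], prob=0.001),
            PtSpec(pt="pituitary tumour benign", hlt=PITUITARY_HLTS[3], prob=0.001),
            PtSpec(pt="nausea", hlt="gastrointestinal symptoms", prob=0.08),
            PtSpec(pt="diarrhoea", hlt="gastrointestinal symptoms", prob=0.06),
            PtSpec(pt="rash", hlt="skin reactions", prob=0.06),
            PtSpec(pt="pyrexia", hlt="general symptoms", prob=0.05),
            PtSpec(pt="hepatic function abnormal", hlt="hepatic disorders", prob=0.04),
        ],
        associations=[
            Association(drug="ipilimumab", hlt=PITUITARY_HLTS[0], rate_ratio=40.0,
                        women_multiplier=2.0, onset_alpha=120.0, onset_beta=1.6),
        ],
        seed=seed,
    )
    db, _ = generate(config)
    return db, config.term_map(), config


def write_tables(db: ReportDatabase, term_map: TermMap, outdir: str | Path) -> dict:
    """Write the four JADER-layout CSVs plus the term map; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{k}.csv" for k in ("demo", "drug", "reac", "hist")}

    db.cases.to_csv(paths["demo"], index=False)
    drugs = db.drugs.copy()
    drugs["admin_start_date"] = drugs["admin_start_date"].dt.strftime("%Y-%m-%d")
    drugs.to_csv(paths["drug"], index=False)
    events = db.events.copy()
    events["onset_date"] = events["onset_date"].dt.strftime("%Y-%m-%d")
    events.to_csv(paths["reac"], index=False)
    hist = db.hist if db.hist is not None else pd.DataFrame(columns=["case_id", "disease"])
    hist.to_csv(paths["hist"], index=False)

    paths["term_map"] = outdir / "term_map.csv"
    term_map.to_frame().to_csv(paths["term_map"], index=False)
    return paths
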