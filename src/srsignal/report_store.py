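"""Load, validate and query a JADER-shaped spontaneous-report database.

The Japanese Adverse Drug Event Report database (JADER) is distributed by
the PMDA as four linked comma-separated tables: a case list (``demo``),
drug mentions (``drug``), adverse-event mentions (``reac``) and primary
disease (``hist``).  This module reads those tables into a validated
in-memory :class:`ReportDatabase`, restricts drug mentions to
reporter-designated *suspect* drugs, and rolls MedDRA preferred terms (PTs)
up to high-level terms (HLTs) through a user-supplied :class:`TermMap`.

MedDRA content is licensed and is never bundled: the PT→HLT map must be
supplied by the user (or by the synthetic-data generator in tests).

The counting unit throughout is the case/report: the database total
``n_reports`` is the N++ denominator of every downstream contingency table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Dialect",
    "TermMap",
    "ReportDatabase",
    "SchemaError",
    "ReferentialIntegrityError",
    "load_database",
    "restrict_to_suspect",
    "flag_event_group",
    "normalize_drug_name",
]

SEX_LEVELS = ("women", "men", "unknown")
INVOLVEMENT_LEVELS = ("suspect", "concomitant", "interaction")

#: Recognized raw spellings of the sex field (case-folded) → canonical level.
_SEX_VOCAB = {
    "women": "women", "woman": "women", "female": "women", "f": "women",
    "men": "men", "man": "men", "male": "men", "m": "men",
    "unknown": "unknown", "": "unknown",
}

_INVOLVEMENT_VOCAB = {
    "suspect": "suspect", "suspect drug": "suspect",
    "concomitant": "concomitant", "concomitant drug": "concomitant",
    "interaction": "interaction",
}


class SchemaError(ValueError):
    """A required table or column is missing."""


class ReferentialIntegrityError(ValueError):
    """A drug or event mention references a case absent from the case list."""


def normalize_drug_name(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Trim, case-fold, and optionally map brand/salt variants to one generic name."""
    key = str(name).strip().casefold()
    if synonyms:
        key = synonyms.get(key, key)
    return key


@dataclass(frozen=True)
class Dialect:
    """Table-format options for the four input tables.

    ``column_map`` renames source columns to the canonical names used here
    (``case_id``, ``sex``, ``generic_name``, ``involvement``,
    ``admin_start_date``, ``pt_name``, ``onset_date``, ``outcome``,
    ``report_quarter``).  PMDA files carry Japanese headers and CP932
    encoding; supply those through ``column_map`` and ``encoding``.
    """

    delimiter: str = ","
    encoding: str = "utf-8"
    column_map: Mapping[str, str] = field(default_factory=dict)
    date_format: str = "%Y-%m-%d"


@dataclass(frozen=True)
class TermMap:
    """A preferred-term → high-level-term mapping (each PT to exactly one HLT)."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))

    @classmethod
    def from_csv(cls, path: str | Path, dialect: Dialect = Dialect()) -> "TermMap":
        """Read a two-column (pt_name, hlt_name) CSV."""
        df = pd.read_csv(path, sep=dialect.delimiter, encoding=dialect.encoding)
        df = df.rename(columns=dict(dialect.column_map))
        for col in ("pt_name", "hlt_name"):
            if col not in df.columns:
                raise SchemaError(f"term map {path}: missing required column {col!r}")
        dup = df["pt_name"][df["pt_name"].duplicated()]
        if not dup.empty:
            raise SchemaError(f"term map: PTs mapped more than once: {sorted(set(dup))}")
        return cls(dict(zip(df["pt_name"], df["hlt_name"])))

    @property
    def hlts(self) -> frozenset:
        return frozenset(self.entries.values())

    def hlt_of(self, pt_name: str) -> str | None:
        """HLT for a PT, or None if the PT is unmapped."""
        return self.entries.get(pt_name)

    def pts_in(self, hlt_name: str) -> frozenset:
        return frozenset(pt for pt, h in self.entries.items() if h == hlt_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pt_name": list(self.entries), "hlt_name": list(self.entries.values())}
        )


@dataclass
class ReportDatabase:
    """Validated case-level store of demographics, drug and event mentions.

    ``cases`` has columns (case_id, sex, report_quarter); ``drugs`` has
    (case_id, generic_name, involvement, admin_start_date); ``events`` has
    (case_id, pt_name, onset_date, outcome).  ``hist``, when present, is
    stored untouched and used by no statistic.
    """

    cases: pd.DataFrame
    drugs: pd.DataFrame
    events: pd.DataFrame
    hist: pd.DataFrame | None = None
    drug_synonyms: Mapping[str, str] = field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        """Total report count — the N++ of the signal-detection contingency table."""
        return len(self.cases)

    def validate(self) -> "ReportDatabase":
        """Check invariants; raise on violation, return self for chaining."""
        if self.cases["case_id"].duplicated().any():
            dups = self.cases["case_id"][self.cases["case_id"].duplicated()]
            raise ReferentialIntegrityError(
                f"duplicate case_id in case list: {sorted(set(dups))[:5]}"
            )
        bad_sex = set(self.cases["sex"]) - set(SEX_LEVELS)
        if bad_sex:
            raise SchemaError(f"unnormalized sex levels: {bad_sex}")
        known = set(self.cases["case_id"])
        for name, table in (("drug", self.drugs), ("reac", self.events)):
            orphans = set(table["case_id"]) - known
            if orphans:
                raise ReferentialIntegrityError(
                    f"{name} table references case_ids absent from demo: "
                    f"{sorted(orphans)[:5]}"
                )
        bad_inv = set(self.drugs["involvement"]) - set(INVOLVEMENT_LEVELS)
        if bad_inv:
            raise SchemaError(f"unnormalized involvement levels: {bad_inv}")
        if (self.events["pt_name"].astype(str).str.len() == 0).any():
            raise SchemaError("empty pt_name in event table")
        return self

    def summary(self) -> pd.DataFrame:
        """Row counts and missingness rates per table, for run logs."""
        rows = [
            ("cases", len(self.cases), float(self.cases["sex"].eq("unknown").mean()) if len(self.cases) else 0.0),
            ("drug_mentions", len(self.drugs), float(self.drugs["admin_start_date"].isna().mean()) if len(self.drugs) else 0.0),
            ("event_mentions", len(self.events), float(self.events["onset_date"].isna().mean()) if len(self.events) else 0.0),
        ]
        return pd.DataFrame(rows, columns=["table", "n_rows", "missing_rate"])


def _read_table(path: str | Path, dialect: Dialect, required: Iterable[str],
                table: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"required table {table!r} not found at {path}")
    df = pd.read_csv(path, sep=dialect.delimiter, encoding=dialect.encoding,
                     dtype=str, keep_default_na=False)
    df = df.rename(columns=dict(dialect.column_map))
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"table {table!r}: missing required column {col!r}")
    return df


def _parse_dates(series: pd.Series, date_format: str) -> pd.Series:
    # Partial dates (e.g. year-month only, as occur in real JADER) fail the
    # exact format and coerce to NaT: treated as missing, never as a guess.
    return pd.to_datetime(series.replace("", None), format=date_format, errors="coerce")


def load_database(
    table_paths: Mapping[str, str | Path],
    dialect: Dialect = Dialect(),
    drug_synonyms: Mapping[str, str] | None = None,
) -> ReportDatabase:
    """Load the demo/drug/reac (and optional hist) tables into a validated database.

    Parameters
    ----------
    table_paths
        Mapping with keys ``demo``, ``drug``, ``reac`` and optionally ``hist``.
    dialect
        Delimiter, encoding, column renames and date format.
    drug_synonyms
        Optional raw-name → generic-name map applied on top of trim/case-fold
        normalization of ``generic_name``.

    Rows with blank case identifiers are dropped and counted in the log;
    sex values outside the recognized vocabulary become ``unknown``.
    """
    for key in ("demo", "drug", "reac"):
        if key not in table_paths:
            raise FileNotFoundError(f"required table {key!r} not in table_paths")

    demo = _read_table(table_paths["demo"], dialect, ["case_id", "sex"], "demo")
    drug = _read_table(table_paths["drug"], dialect,
                       ["case_id", "generic_name", "involvement"], "drug")
    reac = _read_table(table_paths["reac"], dialect, ["case_id", "pt_name"], "reac")

    synonyms = {normalize_drug_name(k): normalize_drug_name(v)
                for k, v in (drug_synonyms or {}).items()}

    frames = {}
    for name, df in (("demo", demo), ("drug", drug), ("reac", reac)):
        bad = df["case_id"].str.strip().eq("")
        if bad.any():
            logger.warning("%s: dropped %d rows with blank case_id", name, int(bad.sum()))
        frames[name] = df.loc[~bad].copy()
    demo, drug, reac = frames["demo"], frames["drug"], frames["reac"]

    sex_raw = demo["sex"].astype(str).str.strip().str.casefold()
    sex = sex_raw.map(_SEX_VOCAB)
    unrecognized = sex.isna()
    if unrecognized.any():
        logger.warning("demo: %d unrecognized sex values mapped to 'unknown' (e.g. %s)",
                       int(unrecognized.sum()),
                       sorted(set(sex_raw[unrecognized]))[:3])
        sex = sex.fillna("unknown")
    demo["sex"] = sex
    if "report_quarter" not in demo.columns:
        demo["report_quarter"] = ""

    drug["generic_name"] = drug["generic_name"].map(
        lambda s: normalize_drug_name(s, synonyms))
    inv = drug["involvement"].astype(str).str.strip().str.casefold().map(_INVOLVEMENT_VOCAB)
    if inv.isna().any():
        bad_vals = sorted(set(drug["involvement"][inv.isna()]))
        raise SchemaError(f"drug table: unrecognized involvement values {bad_vals[:5]}")
    drug["involvement"] = inv
    if "admin_start_date" not in drug.columns:
        drug["admin_start_date"] = ""
    drug["admin_start_date"] = _parse_dates(drug["admin_start_date"], dialect.date_format)

    if "onset_date" not in reac.columns:
        reac["onset_date"] = ""
    reac["onset_date"] = _parse_dates(reac["onset_date"], dialect.date_format)
    if "outcome" not in reac.columns:
        reac["outcome"] = ""

    hist = None
    if "hist" in table_paths and table_paths["hist"] is not None:
        # Loaded and stored for completeness; no statistic consumes it.
        hist = _read_table(table_paths["hist"], dialect, ["case_id"], "hist")

    db = ReportDatabase(
        cases=demo[["case_id", "sex", "report_quarter"]].reset_index(drop=True),
        drugs=drug[["case_id", "generic_name", "involvement", "admin_start_date"]].reset_index(drop=True),
        events=reac[["case_id", "pt_name", "onset_date", "outcome"]].reset_index(drop=True),
        hist=hist,
        drug_synonyms=synonyms,
    )
    return db.validate()


def restrict_to_suspect(db: ReportDatabase) -> ReportDatabase:
    """Keep only suspect-drug mentions; cases and events are untouched.

    A case whose every drug mention was concomitant or interaction keeps its
    row in the case list — it still counts toward N++.  Idempotent.
    """
    kept = db.drugs[db.drugs["involvement"] == "suspect"].reset_index(drop=True)
    return replace(db, drugs=kept)


def flag_event_group(db: ReportDatabase, term_map: TermMap, hlt_name: str) -> pd.Series:
    """Boolean per-case indicator: the case reported ≥1 PT rolling up to ``hlt_name``.

    Duplicate PT mentions within a case count once — the flag depends only on
    the *set* of a case's PTs.
    """
    if hlt_name not in term_map.hlts:
        raise KeyError(
            f"HLT {hlt_name!r} does not occur in the supplied term map "
            f"(known HLTs: {sorted(term_map.hlts)})"
        )
    pts = term_map.pts_in(hlt_name)
    hit_cases = set(db.events.loc[db.events["pt_name"].isin(pts), "case_id"])
    flag = db.cases["case_id"].isin(hit_cases)
    flag.index = db.cases["case_id"].to_numpy()
    flag.name = hlt_name
    return flag
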