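"""2×2 and sex-stratified contingency tables for a (drug, event-group) pair.

Every cell counts distinct cases.  A case is *exposed* if it carries at
least one suspect mention of the target drug (duplicate mentions count
once), and *flagged* if at least one of its PTs rolls up to the target HLT.
The comparator is always "all other reports" in the whole database, so the
grand total of every 2×2 equals the database's ``n_reports`` (N++).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .report_store import ReportDatabase, normalize_drug_name

logger = logging.getLogger(__name__)

__all__ = ["ContingencyTable", "SexStratifiedTable", "build_2x2", "build_sex_tables"]


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts N11/N10/N01/N00 with derived margins."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n1plus(self) -> int:
        """Reports mentioning the target drug."""
        return self.n11 + self.n10

    @property
    def nplus1(self) -> int:
        """Reports mentioning the target event group."""
        return self.n11 + self.n01

    @property
    def nplusplus(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n10, self.n01, self.n00)


@dataclass(frozen=True)
class SexStratifiedTable:
    """Per-sex 2×2 tables; unknown-sex cases sit in neither stratum."""

    women: ContingencyTable
    men: ContingencyTable
    n_unknown_sex: int

    def __post_init__(self) -> None:
        if self.n_unknown_sex < 0:
            raise ValueError("n_unknown_sex must be non-negative")


def _exposed_cases(db: ReportDatabase, drug: str) -> set:
    name = normalize_drug_name(drug, db.drug_synonyms)
    mentions = db.drugs[
        (db.drugs["generic_name"] == name) & (db.drugs["involvement"] == "suspect")
    ]
    return set(mentions["case_id"])


def _count_cells(cases: pd.DataFrame, exposed: set, flag: pd.Series) -> ContingencyTable:
    ids = cases["case_id"]
    is_exposed = ids.isin(exposed).to_numpy()
    is_flagged = flag.reindex(ids).fillna(False).to_numpy(dtype=bool)
    n11 = int((is_exposed & is_flagged).sum())
    n10 = int((is_exposed & ~is_flagged).sum())
    n01 = int((~is_exposed & is_flagged).sum())
    n00 = int((~is_exposed & ~is_flagged).sum())
    return ContingencyTable(n11, n10, n01, n00)


def build_2x2(db: ReportDatabase, drug: str, event_flag: pd.Series) -> ContingencyTable:
    """Count the 2×2 cells for one (drug, event-group) pair over all reports.

    ``event_flag`` is the per-case indicator from
    :func:`srsignal.report_store.flag_event_group` (indexed by case_id).
    A drug absent from the database yields a valid table with n11 = n10 = 0.
    """
    exposed = _exposed_cases(db, drug)
    if not exposed:
        logger.info("drug %r has no suspect mentions; exposed margin is 0", drug)
    return _count_cells(db.cases, exposed, event_flag)


def build_sex_tables(db: ReportDatabase, drug: str, event_flag: pd.Series) -> SexStratifiedTable:
    """Sex-stratified 2×2 tables (the 4×2 layout of the subgroup contrast).

    Cases with unknown sex enter neither stratum and are tallied in
    ``n_unknown_sex``; women.nplusplus + men.nplusplus + n_unknown_sex
    equals the database total.
    """
    exposed = _exposed_cases(db, drug)
    women = _count_cells(db.cases[db.cases["sex"] == "women"], exposed, event_flag)
    men = _count_cells(db.cases[db.cases["sex"] == "men"], exposed, event_flag)
    n_unknown = int((db.cases["sex"] == "unknown").sum())
    return SexStratifiedTable(women=women, men=men, n_unknown_sex=n_unknown)
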