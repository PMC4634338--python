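"""Longitudinal study design: visit schedule, scan identities, pair enumeration.

The study design emulated throughout this package is a two-group
observational cohort (Alzheimer's disease cases and healthy controls)
scanned at nine visits over two years, with back-to-back duplicate scans
at three of the visits.  Scans are identified by (subject, visit, scan)
triples; "direct" change measures are made over ordered scan pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Days per week over days per Julian year; fixed conversion used everywhere.
WEEKS_TO_YEARS = 7.0 / 365.25

#: Default visit schedule in weeks from baseline.
DEFAULT_VISIT_WEEKS = (0, 2, 6, 12, 26, 38, 52, 78, 104)

#: Visits (by week) at which a second back-to-back scan is acquired.
DEFAULT_REPEAT_WEEKS = (0, 6, 38)


class DesignError(ValueError):
    """Raised for inconsistent study-design inputs."""


@dataclass(frozen=True)
class StudyDesign:
    """Maximal visit schedule and group sizes of a longitudinal cohort.

    Individual subjects may attend any subset of visits; the design only
    fixes the schedule that attendance masks index into.

    Parameters
    ----------
    visit_weeks : sequence of int
        Strictly increasing visit times in weeks; first element must be 0.
    repeat_scan_visits : sequence of int
        1-based visit indices at which two same-day scans are taken.
    n_cases, n_controls : int
        Group sizes (cases = patients, controls = healthy).
    """

    visit_weeks: tuple = DEFAULT_VISIT_WEEKS
    repeat_scan_visits: tuple = ()
    n_cases: int = 46
    n_controls: int = 23

    def __post_init__(self):
        weeks = tuple(self.visit_weeks)
        object.__setattr__(self, "visit_weeks", weeks)
        if not weeks or weeks[0] != 0:
            raise DesignError("visit schedule must start at week 0")
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise DesignError("visit_weeks must be strictly increasing")
        if not self.repeat_scan_visits:
            rep = tuple(
                j for j, w in enumerate(weeks, start=1) if w in DEFAULT_REPEAT_WEEKS
            )
            object.__setattr__(self, "repeat_scan_visits", rep)
        else:
            rep = tuple(sorted(self.repeat_scan_visits))
            object.__setattr__(self, "repeat_scan_visits", rep)
            if any(j < 1 or j > len(weeks) for j in rep):
                raise DesignError("repeat_scan_visits outside visit index range")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise DesignError("group sizes must be positive")

    @property
    def n_visits(self) -> int:
        return len(self.visit_weeks)

    @property
    def n_subjects(self) -> int:
        return self.n_cases + self.n_controls

    def scans_at_visit(self, j: int) -> int:
        """Number of scans acquired at 1-based visit index ``j``."""
        self._check_visit(j)
        return 2 if j in self.repeat_scan_visits else 1

    def visit_time_years(self, j: int) -> float:
        """Time of visit ``j`` (1-based) in years from baseline."""
        self._check_visit(j)
        return self.visit_weeks[j - 1] * WEEKS_TO_YEARS

    def all_scans(self, subject) -> list["ScanId"]:
        """Every scan of the full schedule for one subject."""
        return [
            ScanId(subject, j, k)
            for j in range(1, self.n_visits + 1)
            for k in range(1, self.scans_at_visit(j) + 1)
        ]

    def _check_visit(self, j: int) -> None:
        if not 1 <= j <= self.n_visits:
            raise DesignError(f"visit index {j} outside 1..{self.n_visits}")


@dataclass(frozen=True, order=True)
class ScanId:
    """Identity of one scan: subject, 1-based visit index, scan index (1 or 2)."""

    subject: str
    visit: int
    scan: int = 1

    def __post_init__(self):
        object.__setattr__(self, "subject", str(self.subject))
        if self.visit < 1:
            raise DesignError("visit index must be >= 1")
        if self.scan not in (1, 2):
            raise DesignError("scan index must be 1 or 2")


@dataclass(frozen=True)
class ScanPair:
    """An ordered pair of scans of one subject over which change is measured."""

    start: ScanId
    end: ScanId
    direction: str = "forward"

    def __post_init__(self):
        if self.start.subject != self.end.subject:
            raise DesignError("scan pair must be within one subject")
        if self.start == self.end:
            raise DesignError("scan pair must involve two distinct scans")
        if self.direction not in ("forward", "backward"):
            raise DesignError("direction must be 'forward' or 'backward'")

    @property
    def same_day(self) -> bool:
        return self.start.visit == self.end.visit

    def reversed(self) -> "ScanPair":
        other = "backward" if self.direction == "forward" else "forward"
        return ScanPair(self.end, self.start, other)


def visit_time_years(design: StudyDesign, j: int) -> float:
    """Time of the ``j``-th visit in years (weeks x 7/365.25)."""
    return design.visit_time_years(j)


def enumerate_pairs(
    scans: Sequence[ScanId], include_same_day: bool = True
) -> list[ScanPair]:
    """All unordered scan pairs of one subject, oriented forward.

    Forward means the start scan precedes the end scan in (visit, scan)
    order; for same-day pairs the lower scan index is the start.  With
    ``s`` scans this yields s(s-1)/2 pairs; dropping same-day pairs
    removes one pair per repeat-scan visit attended.
    """
    scans = list(scans)
    if len(set(scans)) != len(scans):
        raise DesignError("duplicate ScanId in scan list")
    subjects = {s.subject for s in scans}
    if len(subjects) > 1:
        raise DesignError(f"scans span multiple subjects: {sorted(subjects)}")
    ordered = sorted(scans, key=lambda s: (s.visit, s.scan))
    pairs = []
    for a in range(len(ordered)):
        for b in range(a + 1, len(ordered)):
            pair = ScanPair(ordered[a], ordered[b], "forward")
            if not include_same_day and pair.same_day:
                continue
            pairs.append(pair)
    return pairs


@dataclass
class ExclusionList:
    """Scans excluded from analysis on quality grounds.

    Exclusion removes every volume record of an excluded scan and every
    pair record whose start or end is excluded.
    """

    excluded_scans: set = field(default_factory=set)

    def __contains__(self, scan: ScanId) -> bool:
        return scan in self.excluded_scans

    @classmethod
    def from_tuples(cls, triples: Iterable[tuple]) -> "ExclusionList":
        return cls({ScanId(*t) for t in triples})


@dataclass
class ExclusionReport:
    """Accounting of what an exclusion pass removed."""

    n_scan_records_removed: int = 0
    n_pair_records_removed: int = 0
    unknown_scans: list = field(default_factory=list)


def _scan_cols(frame: pd.DataFrame, prefix: str = "") -> list[str]:
    return [f"{prefix}visit", f"{prefix}scan"]


def apply_exclusions(
    records: pd.DataFrame, exclusions: ExclusionList
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop rows touching excluded scans from a volumes or changes table.

    Accepts either a volumes table (columns subject/visit/scan) or a
    changes table (subject/start_visit/start_scan/end_visit/end_scan).
    Returns the filtered table and a removal report.  Excluding a scan
    absent from the table is a no-op logged as a warning.
    """
    report = ExclusionReport()
    if not exclusions.excluded_scans:
        return records, report

    excl = {(s.subject, s.visit, s.scan) for s in exclusions.excluded_scans}

    if "start_visit" in records.columns:
        start = list(
            zip(records["subject"], records["start_visit"], records["start_scan"])
        )
        end = list(zip(records["subject"], records["end_visit"], records["end_scan"]))
        hit = [s in excl or e in excl for s, e in zip(start, end)]
        present = set(start) | set(end)
        report.n_pair_records_removed = int(sum(hit))
    else:
        keys = list(zip(records["subject"], records["visit"], records["scan"]))
        hit = [k in excl for k in keys]
        present = set(keys)
        report.n_scan_records_removed = int(sum(hit))

    for s in sorted(excl):
        if s not in present:
            report.unknown_scans.append(s)
            logger.warning("excluded scan %s not present in table; ignoring", s)

    keep = records.loc[[not h for h in hit]].reset_index(drop=True)
    return keep, report
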