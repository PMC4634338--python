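"""Readers and writers for the challenge-style tabular formats.

Two plain-CSV tables carry all data:

* **volumes** — one row per scan:
  ``subject, group, visit, scan, weeks, structure, volume``
* **changes** — one row per ordered scan pair and direction:
  ``subject, group, start_visit, start_scan, end_visit, end_scan,
  direction, structure, change, change_kind``

``change_kind`` declares the scale of the ``change`` column:
``ln_percent`` (already 100*ln-scale), ``percent`` (simple percent
change) or ``volume`` (absolute volume difference, which requires the
volumes table to standardize).  Readers normalize everything to the
100*ln scale, where volume loss is negative; ventricular "atrophy" is
expansion and only made positive at the presentation layer.

Exclusion lists come in two dialects: explicit ``subject,visit,scan``
columns, or compact ``subject_LETTER`` codes where the letter indexes
the chronological scan sequence of the full schedule (A = first
baseline scan, B = second baseline scan, ...).
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ExclusionList, ScanId, StudyDesign
from .reliability import c_direct, c_direct_percent

VOLUME_COLUMNS = ["subject", "group", "visit", "scan", "weeks", "structure", "volume"]
CHANGE_COLUMNS = [
    "subject", "group", "start_visit", "start_scan", "end_visit", "end_scan",
    "direction", "structure", "change", "change_kind",
]
CHANGE_KINDS = ("ln_percent", "percent", "volume")


class FormatError(ValueError):
    """Malformed input table."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")


def read_volumes(path, design: StudyDesign | None = None) -> pd.DataFrame:
    """Read and validate a volumes CSV; adds ``time_years`` and ``y``."""
    df = pd.read_csv(path)
    _require_columns(df, ["subject", "visit", "scan", "weeks", "volume"], path)
    bad = df.index[df["volume"] <= 0]
    if len(bad):
        raise FormatError(
            f"{path}: non-positive volume at row {int(bad[0]) + 2} (1-based with header)"
        )
    key_cols = ["subject", "visit", "scan"]
    if "structure" in df.columns:
        key_cols.append("structure")
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise FormatError(f"{path}: duplicate scan key at row {row}")
    df["time_years"] = df["weeks"].astype(float) * 7.0 / 365.25
    df["y"] = 100.0 * np.log(df["volume"].astype(float))
    return df


def write_volumes(df: pd.DataFrame, path) -> None:
    cols = [c for c in VOLUME_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def read_changes(
    path,
    change_kind: str | None = None,
    volumes: pd.DataFrame | None = None,
    design: StudyDesign | None = None,
) -> pd.DataFrame:
    """Read a changes CSV, standardizing ``change`` to the 100*ln scale.

    ``change_kind`` overrides (or supplies, if absent) the file's
    declared kind.  Kind ``volume`` requires the matching volumes table
    to provide each pair's start-scan volume.  ``delta_t_years`` is
    taken from the file or derived from a supplied design.
    """
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["subject", "start_visit", "start_scan", "end_visit", "end_scan",
         "direction", "change"],
        path,
    )
    if change_kind is None:
        if "change_kind" not in df.columns:
            raise FormatError(f"{path}: change_kind neither declared nor supplied")
        kinds = df["change_kind"].unique()
        if len(kinds) != 1:
            raise FormatError(f"{path}: mixed change_kind values {list(kinds)}")
        change_kind = str(kinds[0])
    if change_kind not in CHANGE_KINDS:
        raise FormatError(f"{path}: unknown change_kind {change_kind!r}")

    change = df["change"].astype(float).to_numpy()
    if change_kind == "percent":
        df["change"] = c_direct_percent(change)
    elif change_kind == "volume":
        if volumes is None:
            raise FormatError(
                f"{path}: change_kind 'volume' requires the volumes table"
            )
        key = ["subject", "visit", "scan"]
        if "structure" in df.columns and "structure" in volumes.columns:
            key.append("structure")
        vb = volumes.set_index(key)["volume"]
        idx = list(
            zip(*[df["subject"]]
                + [df["start_visit"], df["start_scan"]]
                + ([df["structure"]] if len(key) == 4 else []))
        )
        try:
            v_start = vb.loc[idx].to_numpy(dtype=float)
        except KeyError as exc:
            raise FormatError(f"{path}: pair references unknown scan {exc}") from exc
        df["change"] = c_direct(v_start, change)
    df["change_kind"] = "ln_percent"

    if "delta_t_years" not in df.columns:
        if design is None:
            raise FormatError(
                f"{path}: delta_t_years absent and no design supplied"
            )
        t = {j: design.visit_time_years(j) for j in range(1, design.n_visits + 1)}
        df["delta_t_years"] = [
            t[int(e)] - t[int(s)]
            for s, e in zip(df["start_visit"], df["end_visit"])
        ]
    return df


def write_changes(df: pd.DataFrame, path) -> None:
    cols = [c for c in CHANGE_COLUMNS if c in df.columns]
    extra = [c for c in ("delta_t_years",) if c in df.columns]
    df.to_csv(path, index=False, columns=cols + extra)


# ---------------------------------------------------------------------------
# Exclusion lists
# ---------------------------------------------------------------------------


def default_letter_map(design: StudyDesign) -> dict[str, tuple[int, int]]:
    """Letter -> (visit, scan) over the chronological full-schedule scans."""
    letters = string.ascii_uppercase
    scans = design.all_scans("_")
    if len(scans) > len(letters):
        raise ValueError("schedule too long for single-letter codes")
    return {letters[i]: (s.visit, s.scan) for i, s in enumerate(scans)}


def read_exclusions(
    path, design: StudyDesign | None = None
) -> ExclusionList:
    """Read an exclusion list in either dialect.

    Explicit dialect: CSV with subject,visit,scan columns.  Compact
    dialect: one ``subject_LETTER`` code per line (requires a design to
    resolve letters).
    """
    text = Path(path).read_text().strip()
    if not text:
        return ExclusionList()
    first = text.splitlines()[0]
    if "visit" in first and "scan" in first:
        df = pd.read_csv(path)
        _require_columns(df, ["subject", "visit", "scan"], path)
        return ExclusionList(
            {
                ScanId(str(r.subject), int(r.visit), int(r.scan))
                for r in df.itertuples()
            }
        )
    if design is None:
        raise FormatError(f"{path}: letter-coded exclusions need a study design")
    letter_map = default_letter_map(design)
    scans = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        code = line.strip().strip(",")
        if not code or code.startswith("#"):
            continue
        try:
            subject, letter = code.rsplit("_", 1)
            visit, scan = letter_map[letter.upper()]
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path}: bad exclusion code {code!r} at line {lineno}") from exc
        scans.add(ScanId(subject, visit, scan))
    return ExclusionList(scans)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of (``volumes_path``, ``changes_path``) inputs or
    ``simulate: true`` must be active.
    """

    simulate: bool = True
    volumes_path: str | None = None
    changes_path: str | None = None
    exclusions_path: str | None = None
    change_kind: str | None = None
    structures: tuple = ("brain",)
    followups: tuple = (0.5, 1.0, 2.0)
    n_resamples: int = 2000
    seed: int = 0
    output_dir: str = "results"
    run_bootstrap: bool = True

    def __post_init__(self):
        has_files = self.volumes_path is not None or self.changes_path is not None
        if self.simulate and has_files:
            raise ValueError("config must use either simulation or input files")
        if not self.simulate and not has_files:
            raise ValueError("config needs input files when not simulating")
        self.structures = tuple(self.structures)
        self.followups = tuple(float(f) for f in self.followups)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            "simulate": self.simulate,
            "volumes_path": self.volumes_path,
            "changes_path": self.changes_path,
            "exclusions_path": self.exclusions_path,
            "change_kind": self.change_kind,
            "structures": list(self.structures),
            "followups": list(self.followups),
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "run_bootstrap": self.run_bootstrap,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
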