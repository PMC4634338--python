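"""Synthetic longitudinal volume and direct-change data.

Generates datasets with the exact statistical structure assumed by the
analysis models in :mod:`atrophystats.volume_model` and
:mod:`atrophystats.direct_model`, so that every downstream stage can be
exercised and validated without access to any imaging data.

All simulation happens on the ``100*ln(volume)`` scale, where differences
approximate percent change and atrophy is negative; raw volumes are
obtained by exponentiation.  A volume observation of subject ``i`` at
visit ``j``, scan ``k`` is

    y_ijk = alpha_i + (beta + b_i) * t_ij + d_ij + e_ijk

with subject-specific level ``alpha_i``, mean rate ``beta`` (%/year),
between-subject rate deviation ``b_i ~ N(0, sigma2_b)``, visit effect
``d_ij ~ N(0, sigma2_d)`` and scan effect ``e_ijk ~ N(0, sigma2_e)``.

A direct (registration-based) change measure over the ordered scan pair
(j1,k1) -> (j2,k2) is

    c = (beta + b_i) * (t_ij2 - t_ij1) - u_ij1 + u_ij2
        - v_ij1k1 + v_ij2k2 + w

with signed visit effects ``u ~ N(0, sigma2_u)``, signed scan effects
``v ~ N(0, sigma2_v)`` and a pair-specific residual ``w ~ N(0, sigma2_w)``.
Visit and scan effects are shared across every pair that touches the
visit or scan in question, which induces the cross-pair covariance the
direct-change model exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import ScanId, StudyDesign, enumerate_pairs

STRUCTURES = ("brain", "ventricle", "hippo_l", "hippo_r")
GROUPS = ("AD", "control")


@dataclass(frozen=True)
class VolumeModelParams:
    """Parameters of the repeated-volume model on the 100*ln scale.

    beta is the mean rate of change in %/year; sigma2_b the
    between-subject rate variance in (%/yr)^2; sigma2_d and sigma2_e
    the visit- and scan-level variances in (%)^2; alpha_mean/alpha_sd
    the distribution of subject baseline levels (100*ln ml).
    """

    beta: float
    sigma2_b: float
    sigma2_d: float
    sigma2_e: float
    alpha_mean: float = 100.0 * math.log(1000.0)
    alpha_sd: float = 10.0

    def __post_init__(self):
        for name in ("sigma2_b", "sigma2_d", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.alpha_sd < 0:
            raise ValueError("alpha_sd must be non-negative")

    @property
    def within_aggregate(self) -> float:
        """Within-subject variance of a 1-year rate: 2*sigma2_d + 2*sigma2_e."""
        return 2.0 * self.sigma2_d + 2.0 * self.sigma2_e


@dataclass(frozen=True)
class DirectModelParams:
    """Parameters of the repeated direct-change model on the 100*ln scale."""

    beta: float
    sigma2_b: float
    sigma2_u: float
    sigma2_v: float
    sigma2_w: float
    symmetry_noise_sd: float = 0.0

    def __post_init__(self):
        for name in ("sigma2_b", "sigma2_u", "sigma2_v", "sigma2_w"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.symmetry_noise_sd < 0:
            raise ValueError("symmetry_noise_sd must be non-negative")

    @property
    def within_aggregate(self) -> float:
        """Within-subject variance of a 1-year rate: 2u + 2v + w."""
        return 2.0 * self.sigma2_u + 2.0 * self.sigma2_v + self.sigma2_w


# ---------------------------------------------------------------------------
# Default parameter presets.
#
# Mean rates reflect the ranges reported for modern atrophy-measurement
# pipelines on serial 1.5T MRI of AD patients and matched elderly controls:
# whole-brain loss of 1.4-2.2 %/yr (AD) vs 0.35-0.67 %/yr (controls),
# ventricular expansion of 4.6-10.2 %/yr vs 1.2-3.4 %/yr, and hippocampal
# loss of 1.5-7 %/yr vs 0.4-1.4 %/yr.  Between- and within-subject variance
# components (in (%/yr)^2, the within component referred to one year of
# follow-up) are taken from representative published technique estimates in
# the AD group: a boundary-shift-integral style whole-brain measure
# (0.47 / 0.19), segmentation-based ventricle (17.17 / 3.94) and hippocampus
# (4.24 / 12.00 left, 4.60 / 10.05 right) volumetry, and direct-change
# measures for ventricle (3.18 / 0.82) and hippocampi (10.00 / 6.93 left,
# 8.50 / 7.51 right).
# ---------------------------------------------------------------------------

#: (beta_AD, beta_control) in %/yr per structure.
_PRESET_BETA = {
    "brain": (-1.8, -0.51),
    "ventricle": (7.0, 2.3),
    "hippo_l": (-4.0, -0.9),
    "hippo_r": (-4.0, -0.9),
}

#: (between, within-aggregate) variance components of the AD group.
_PRESET_VOLUME_VAR = {
    "brain": (0.47, 0.19),
    "ventricle": (17.17, 3.94),
    "hippo_l": (4.24, 12.00),
    "hippo_r": (4.60, 10.05),
}
_PRESET_DIRECT_VAR = {
    "brain": (0.47, 0.19),
    "ventricle": (3.18, 0.82),
    "hippo_l": (10.00, 6.93),
    "hippo_r": (8.50, 7.51),
}

#: (typical baseline volume in ml, SD of 100*ln(volume)).
_PRESET_BASELINE = {
    "brain": (1100.0, 8.0),
    "ventricle": (40.0, 40.0),
    "hippo_l": (3.0, 15.0),
    "hippo_r": (3.0, 15.0),
}

# Controls are assumed to have the same measurement-error components as AD
# (error is a property of the technique, not the disease) but a more
# homogeneous rate distribution: between-subject variance scaled by 1/4.
_CONTROL_BETWEEN_SCALE = 0.25

# Within-aggregate partitions (see docs/methods.md): for volumes
# 2*sigma2_d : 2*sigma2_e = 0.6 : 0.4; for direct changes
# 2*sigma2_u : 2*sigma2_v : sigma2_w = 0.5 : 0.3 : 0.2.
_VOLUME_SPLIT = (0.6, 0.4)
_DIRECT_SPLIT = (0.5, 0.3, 0.2)


def default_presets(
    structure: str, group: str
) -> tuple[VolumeModelParams, DirectModelParams]:
    """Documented default simulation parameters for a structure and group."""
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; one of {STRUCTURES}")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; one of {GROUPS}")
    is_ad = group == "AD"
    beta = _PRESET_BETA[structure][0 if is_ad else 1]
    scale = 1.0 if is_ad else _CONTROL_BETWEEN_SCALE

    vb, vw = _PRESET_VOLUME_VAR[structure]
    ml, asd = _PRESET_BASELINE[structure]
    vol = VolumeModelParams(
        beta=beta,
        sigma2_b=vb * scale,
        sigma2_d=_VOLUME_SPLIT[0] * vw / 2.0,
        sigma2_e=_VOLUME_SPLIT[1] * vw / 2.0,
        alpha_mean=100.0 * math.log(ml),
        alpha_sd=asd,
    )
    db, dw = _PRESET_DIRECT_VAR[structure]
    direct = DirectModelParams(
        beta=beta,
        sigma2_b=db * scale,
        sigma2_u=_DIRECT_SPLIT[0] * dw / 2.0,
        sigma2_v=_DIRECT_SPLIT[1] * dw / 2.0,
        sigma2_w=_DIRECT_SPLIT[2] * dw,
    )
    return vol, direct


# ---------------------------------------------------------------------------
# Cohort layout and attendance
# ---------------------------------------------------------------------------


def make_subjects(design: StudyDesign) -> list[tuple[str, str]]:
    """(subject id, group) for every subject of the design, cases first."""
    subjects = [(f"AD{i + 1:03d}", "AD") for i in range(design.n_cases)]
    subjects += [(f"HC{i + 1:03d}", "control") for i in range(design.n_controls)]
    return subjects


def default_attendance(
    design: StudyDesign, late_fraction: float = 0.5
) -> dict[str, tuple[int, ...]]:
    """Per-subject attended visit indices.

    Every subject completes the schedule through 52 weeks; a fixed
    ``late_fraction`` of each group (deterministically, every other
    subject) also attends the extension visits beyond 52 weeks.
    """
    core = tuple(
        j for j, w in enumerate(design.visit_weeks, start=1) if w <= 52
    )
    full = tuple(range(1, design.n_visits + 1))
    attendance = {}
    for idx, (subj, _group) in enumerate(make_subjects(design)):
        attends_late = (idx % 2 == 0) and late_fraction > 0
        if late_fraction >= 1.0:
            attends_late = True
        attendance[subj] = full if attends_late else core
    return attendance


def _subject_rngs(seed: int, subjects: list) -> dict:
    """Independent per-subject random substreams from one seed.

    Substreams are keyed by position in the cohort, so changing one
    subject's attendance leaves every other subject's draws untouched.
    """
    children = np.random.SeedSequence(seed).spawn(len(subjects))
    return {subj: np.random.default_rng(c) for (subj, _g), c in zip(subjects, children)}


def _attended_scans(design: StudyDesign, subject: str, visits) -> list[ScanId]:
    return [
        ScanId(subject, j, k)
        for j in visits
        for k in range(1, design.scans_at_visit(j) + 1)
    ]


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------


def simulate_volume_dataset(
    design: StudyDesign,
    params_by_group: dict[str, VolumeModelParams],
    attendance: dict | None = None,
    seed: int = 0,
    structure: str = "brain",
) -> pd.DataFrame:
    """Simulate a tidy table of repeated volume measurements.

    Returns one row per (subject, visit, scan) with columns
    subject, group, visit, scan, weeks, time_years, structure, volume,
    and y (the 100*ln(volume) value actually simulated).
    """
    if attendance is None:
        attendance = default_attendance(design)
    subjects = make_subjects(design)
    rngs = _subject_rngs(seed, subjects)

    rows = []
    for subj, group in subjects:
        p = params_by_group[group]
        rng = rngs[subj]
        visits = attendance.get(subj, ())
        alpha = rng.normal(p.alpha_mean, p.alpha_sd)
        b = rng.normal(0.0, math.sqrt(p.sigma2_b)) if p.sigma2_b > 0 else 0.0
        sd_d = math.sqrt(p.sigma2_d)
        sd_e = math.sqrt(p.sigma2_e)
        for j in visits:
            t = design.visit_time_years(j)
            d = rng.normal(0.0, sd_d) if sd_d > 0 else 0.0
            for k in range(1, design.scans_at_visit(j) + 1):
                e = rng.normal(0.0, sd_e) if sd_e > 0 else 0.0
                y = alpha + (p.beta + b) * t + d + e
                rows.append(
                    (subj, group, j, k, design.visit_weeks[j - 1], t, structure, y)
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "subject", "group", "visit", "scan", "weeks", "time_years",
            "structure", "y",
        ],
    )
    frame["volume"] = np.exp(frame["y"] / 100.0)
    return frame


def simulate_direct_dataset(
    design: StudyDesign,
    params_by_group: dict[str, DirectModelParams],
    attendance: dict | None = None,
    seed: int = 0,
    structure: str = "brain",
    include_same_day: bool = True,
    change_kind: str = "ln_percent",
) -> pd.DataFrame:
    """Simulate forward and backward direct change measures for all pairs.

    For each subject, one signed visit effect per attended visit and one
    signed scan effect per scan are drawn once and shared across every
    pair touching them; an independent residual ``w`` is drawn per
    unordered pair.  The backward measure is the negated forward measure
    plus ``N(0, symmetry_noise_sd^2)`` asymmetry noise.

    ``change_kind`` selects the reported scale: ``"ln_percent"`` reports
    the 100*ln-scale change ``c`` itself, ``"percent"`` reports the
    equivalent simple percent change ``100*(exp(c/100)-1)``.
    """
    if change_kind not in ("ln_percent", "percent"):
        raise ValueError("change_kind must be 'ln_percent' or 'percent'")
    if attendance is None:
        attendance = default_attendance(design)
    subjects = make_subjects(design)
    rngs = _subject_rngs(seed, subjects)

    rows = []
    for subj, group in subjects:
        p = params_by_group[group]
        rng = rngs[subj]
        visits = attendance.get(subj, ())
        scans = _attended_scans(design, subj, visits)
        b = rng.normal(0.0, math.sqrt(p.sigma2_b)) if p.sigma2_b > 0 else 0.0
        sd_u = math.sqrt(p.sigma2_u)
        sd_v = math.sqrt(p.sigma2_v)
        sd_w = math.sqrt(p.sigma2_w)
        u = {j: (rng.normal(0.0, sd_u) if sd_u > 0 else 0.0) for j in visits}
        v = {
            (s.visit, s.scan): (rng.normal(0.0, sd_v) if sd_v > 0 else 0.0)
            for s in scans
        }
        for pair in enumerate_pairs(scans, include_same_day=include_same_day):
            s, e = pair.start, pair.end
            dt = design.visit_time_years(e.visit) - design.visit_time_years(s.visit)
            w = rng.normal(0.0, sd_w) if sd_w > 0 else 0.0
            c_fwd = (
                (p.beta + b) * dt
                - u[s.visit] + u[e.visit]
                - v[(s.visit, s.scan)] + v[(e.visit, e.scan)]
                + w
            )
            if p.symmetry_noise_sd > 0:
                c_bwd = -c_fwd + rng.normal(0.0, p.symmetry_noise_sd)
            else:
                c_bwd = -c_fwd
            for direction, c, a, z in (
                ("forward", c_fwd, s, e),
                ("backward", c_bwd, e, s),
            ):
                rows.append(
                    (
                        subj, group, a.visit, a.scan, z.visit, z.scan,
                        direction, dt if direction == "forward" else -dt,
                        structure, c,
                    )
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "subject", "group", "start_visit", "start_scan", "end_visit",
            "end_scan", "direction", "delta_t_years", "structure", "change",
        ],
    )
    if change_kind == "percent":
        frame["change"] = 100.0 * np.expm1(frame["change"] / 100.0)
    frame["change_kind"] = change_kind
    return frame


def constrained(params, between_zero: bool = True):
    """Copy of a parameter set with between-subject (and visit) variance zeroed.

    Mirrors the fallback analysis model in which sigma2_b and the visit
    effect variance are held at zero.
    """
    if isinstance(params, VolumeModelParams):
        return replace(params, sigma2_b=0.0, sigma2_d=0.0)
    if isinstance(params, DirectModelParams):
        return replace(params, sigma2_b=0.0, sigma2_u=0.0)
    raise TypeError("params must be VolumeModelParams or DirectModelParams")
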