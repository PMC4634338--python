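"""End-to-end orchestration: simulate/load -> reliability -> fit -> power -> bootstrap."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import BootstrapSpec, EffectSizePipeline, bootstrap_effect_size_ci
from .design import StudyDesign, apply_exclusions
from .direct_model import fit_direct_model
from .io import (
    RunConfig,
    read_changes,
    read_exclusions,
    read_volumes,
    write_changes,
    write_volumes,
)
from .power import power_table
from .reliability import (
    c_indirect,
    median_with_ci,
    short_interval_test,
    symmetry_difference,
    transitivity_difference,
)
from .synthetic import (
    default_presets,
    simulate_direct_dataset,
    simulate_volume_dataset,
)
from .volume_model import fit_volume_model

logger = logging.getLogger(__name__)


def _pair_changes(volumes: pd.DataFrame, start_key, end_key) -> pd.Series:
    """Per-subject indirect change (100*ln) between two (visit, scan) keys."""
    idx = volumes.set_index(["subject", "visit", "scan"])["volume"]
    out = {}
    for subj in volumes["subject"].unique():
        try:
            vb = idx.loc[(subj,) + tuple(start_key)]
            vr = idx.loc[(subj,) + tuple(end_key)]
        except KeyError:
            continue
        out[subj] = float(c_indirect(vb, vr))
    return pd.Series(out)


def _visit_at_weeks(volumes: pd.DataFrame, weeks: int):
    rows = volumes[volumes["weeks"] == weeks]
    return int(rows["visit"].iloc[0]) if len(rows) else None


def reliability_scorecard(
    volumes: pd.DataFrame | None,
    changes: pd.DataFrame | None,
) -> pd.DataFrame:
    """Tidy per-(group, structure, metric) reliability summary.

    Short-interval metrics (same-day and two-week change, mean with
    t-test) come from the volumes table; symmetry and transitivity
    (median with binomial CI) come from the direct changes table, using
    the baseline and the visits closest to 6 and 12 months after it.
    """
    rows = []

    if volumes is not None:
        for (group, structure), g in volumes.groupby(["group", "structure"]):
            base = _visit_at_weeks(g, 0)
            two_wk = _visit_at_weeks(g, 2)
            specs = []
            if base is not None:
                specs.append(("same_day", (base, 1), (base, 2)))
            if base is not None and two_wk is not None:
                specs.append(("two_week", (base, 1), (two_wk, 1)))
            for interval, s_key, e_key in specs:
                ch = _pair_changes(g, s_key, e_key)
                if len(ch) < 2:
                    continue
                s = short_interval_test(ch.to_numpy(), group, structure, interval)
                rows.append(
                    (group, structure, interval, s.mean_change, *s.ci95,
                     s.n, s.p_value)
                )

    if changes is not None:
        fwd = changes[changes["direction"] == "forward"]
        bwd = changes[changes["direction"] == "backward"]
        for (group, structure), g in fwd.groupby(["group", "structure"]):
            gb = bwd[(bwd["group"] == group) & (bwd["structure"] == structure)]

            def chg(frame, sv, ev):
                sel = frame[
                    (frame["start_visit"] == sv) & (frame["start_scan"] == 1)
                    & (frame["end_visit"] == ev) & (frame["end_scan"] == 1)
                ]
                return sel.set_index("subject")["change"]

            # Milestone visits located by interval from baseline: visit 1 is
            # the identified baseline; r6/r12 are the visits whose forward
            # pair from it spans closest to 0.5 and 1.0 years.
            base_pairs = g[(g["start_visit"] == 1) & (g["start_scan"] == 1)
                           & (g["end_scan"] == 1)]
            if base_pairs.empty:
                continue
            uniq = base_pairs.drop_duplicates("end_visit")
            v_r6 = int(
                uniq.iloc[(uniq["delta_t_years"] - 0.5).abs().argmin()]["end_visit"]
            )
            v_r12 = int(
                uniq.iloc[(uniq["delta_t_years"] - 1.0).abs().argmin()]["end_visit"]
            )

            f_b12 = chg(g, 1, v_r12)
            b_12b = chg(gb, v_r12, 1)
            common = f_b12.index.intersection(b_12b.index)
            if len(common):
                d_sym = symmetry_difference(
                    f_b12.loc[common].to_numpy(), -b_12b.loc[common].to_numpy()
                )
                s = median_with_ci(d_sym, group, structure, "symmetry")
                rows.append(
                    (group, structure, "symmetry", s.median, *s.ci95, s.n, np.nan)
                )
            f_b6 = chg(g, 1, v_r6)
            f_612 = chg(g, v_r6, v_r12)
            common = f_b12.index.intersection(f_b6.index).intersection(f_612.index)
            if len(common):
                d_tr = transitivity_difference(
                    f_b12.loc[common].to_numpy(),
                    f_b6.loc[common].to_numpy(),
                    f_612.loc[common].to_numpy(),
                )
                s = median_with_ci(d_tr, group, structure, "transitivity")
                rows.append(
                    (group, structure, "transitivity", s.median, *s.ci95, s.n, np.nan)
                )

    return pd.DataFrame(
        rows,
        columns=["group", "structure", "metric", "estimate", "ci_low",
                 "ci_high", "n", "p_value"],
    )


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, design: StudyDesign | None = None) -> dict:
    """Execute all requested stages and write result tables.

    Returns a manifest dict (also written as JSON) recording the seed,
    config hash, versions, per-stage timing and exclusion accounting.
    Output tables are deterministic given (config, seed).
    """
    t0 = time.time()
    design = design or StudyDesign()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "package_version": __version__,
        "python": platform.python_version(),
        "stages": {},
    }

    # ------------------------------------------------------------ data
    stage_start = time.time()
    if config.simulate:
        vol_frames, chg_frames = [], []
        for si, structure in enumerate(config.structures):
            params_v = {}
            params_d = {}
            for group in ("AD", "control"):
                pv, pd_ = default_presets(structure, group)
                params_v[group] = pv
                params_d[group] = pd_
            vol_frames.append(
                simulate_volume_dataset(
                    design, params_v, seed=config.seed + 1000 * si,
                    structure=structure,
                )
            )
            chg_frames.append(
                simulate_direct_dataset(
                    design, params_d, seed=config.seed + 1000 * si + 500,
                    structure=structure,
                )
            )
        volumes = pd.concat(vol_frames, ignore_index=True)
        changes = pd.concat(chg_frames, ignore_index=True)
    else:
        volumes = read_volumes(config.volumes_path) if config.volumes_path else None
        changes = (
            read_changes(
                config.changes_path, change_kind=config.change_kind,
                volumes=volumes, design=design,
            )
            if config.changes_path
            else None
        )

    if config.exclusions_path:
        exclusions = read_exclusions(config.exclusions_path, design)
        if volumes is not None:
            volumes, rep_v = apply_exclusions(volumes, exclusions)
            manifest["excluded_scan_records"] = rep_v.n_scan_records_removed
        if changes is not None:
            changes, rep_c = apply_exclusions(changes, exclusions)
            manifest["excluded_pair_records"] = rep_c.n_pair_records_removed
    if volumes is not None:
        write_volumes(volumes, out / "volumes.csv")
    if changes is not None:
        write_changes(changes, out / "changes.csv")
    manifest["stages"]["data"] = round(time.time() - stage_start, 3)

    # ----------------------------------------------------- reliability
    stage_start = time.time()
    scorecard = reliability_scorecard(volumes, changes)
    scorecard.to_csv(out / "reliability.csv", index=False)
    manifest["stages"]["reliability"] = round(time.time() - stage_start, 3)

    # ------------------------------------------------------------ fits
    stage_start = time.time()
    fit_reports = []
    fits: dict = {}
    for structure in config.structures:
        for group in ("AD", "control"):
            if volumes is not None:
                sub = volumes[
                    (volumes["group"] == group)
                    & (volumes["structure"] == structure)
                ]
                fv = fit_volume_model(sub)
                fits[("volume", structure, group)] = fv
                fit_reports.append(
                    {"structure": structure, "group": group, **fv.report()}
                )
            if changes is not None:
                sub = changes[
                    (changes["group"] == group)
                    & (changes["structure"] == structure)
                ]
                fd = fit_direct_model(sub)
                fits[("direct", structure, group)] = fd
                fit_reports.append(
                    {"structure": structure, "group": group, **fd.report()}
                )
    (out / "fits.json").write_text(json.dumps(fit_reports, indent=2, default=float))
    manifest["stages"]["fit"] = round(time.time() - stage_start, 3)

    # ----------------------------------------------------------- power
    stage_start = time.time()
    power_rows = []
    for (model, structure, group), fit in fits.items():
        if group != "AD":
            continue
        ctrl = fits.get((model, structure, "control"))
        if ctrl is None:
            continue
        for res in power_table(
            fit, ctrl, followups=config.followups, structure=structure,
            technique=model,
        ):
            power_rows.append(vars(res))
    power_df = pd.DataFrame(power_rows)
    power_df.to_csv(out / "power.csv", index=False)
    manifest["stages"]["power"] = round(time.time() - stage_start, 3)

    # ------------------------------------------------------- bootstrap
    if config.run_bootstrap:
        stage_start = time.time()
        boot_rows = []
        spec = BootstrapSpec(n_resamples=config.n_resamples, seed=config.seed)
        for structure in config.structures:
            for model, table in (("volume", volumes), ("direct", changes)):
                if table is None:
                    continue
                sub = table[table["structure"] == structure]
                pipe = EffectSizePipeline(model=model, followup_years=1.0)
                ci = bootstrap_effect_size_ci(sub, pipe, spec)
                boot_rows.append(
                    {
                        "structure": structure,
                        "model": model,
                        "followup_years": ci.followup_years,
                        "es_hat": ci.es_hat,
                        "es_ci_low": ci.es_ci[0],
                        "es_ci_high": ci.es_ci[1],
                        "n_total": ci.n_total_hat,
                        "n_total_ci_low": ci.n_total_ci[0],
                        "n_total_ci_high": ci.n_total_ci[1],
                        "n_failed": ci.n_failed,
                        "fallback_used": ci.fallback_used,
                    }
                )
        pd.DataFrame(boot_rows).to_csv(out / "bootstrap.csv", index=False)
        manifest["stages"]["bootstrap"] = round(time.time() - stage_start, 3)

    manifest["total_seconds"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
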