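"""Synthetic-data generator: model structure, determinism, presets."""

import math

import numpy as np
import pandas as pd
import pytest

from atrophystats import StudyDesign
from atrophystats.synthetic import (
    DirectModelParams,
    VolumeModelParams,
    default_attendance,
    default_presets,
    make_subjects,
    simulate_direct_dataset,
    simulate_volume_dataset,
)

NOISE_FREE = VolumeModelParams(
    beta=-2.0, sigma2_b=0.0, sigma2_d=0.0, sigma2_e=0.0,
    alpha_mean=100.0 * math.log(1000.0), alpha_sd=0.0,
)


class TestVolumeSimulation:
    def test_noise_free_model_is_exact(self, full_design):
        """With all variances zero, volume follows 1000*exp(beta*t/100)."""
        params = {"AD": NOISE_FREE, "control": NOISE_FREE}
        df = simulate_volume_dataset(full_design, params, seed=0)
        at_52w = df[df["weeks"] == 52].iloc[0]
        t = 52 * 7 / 365.25
        assert at_52w["volume"] == pytest.approx(1000.0 * math.exp(-0.02 * t), rel=1e-12)
        baseline = df[df["weeks"] == 0]
        assert np.allclose(baseline["volume"], 1000.0)

    def test_same_seed_reproduces(self, full_design, brain_params):
        a = simulate_volume_dataset(full_design, brain_params[0], seed=7)
        b = simulate_volume_dataset(full_design, brain_params[0], seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_volume_dataset(full_design, brain_params[0], seed=8)
        assert not np.allclose(a["volume"], c["volume"])

    def test_attendance_change_leaves_other_subjects_alone(
        self, full_design, brain_params
    ):
        """Per-subject substreams: one subject's mask never perturbs others."""
        att = default_attendance(full_design)
        a = simulate_volume_dataset(full_design, brain_params[0], att, seed=3)
        att2 = dict(att)
        att2["AD002"] = (1, 2)
        b = simulate_volume_dataset(full_design, brain_params[0], att2, seed=3)
        a_others = a[a["subject"] != "AD002"].reset_index(drop=True)
        b_others = b[b["subject"] != "AD002"].reset_index(drop=True)
        pd.testing.assert_frame_equal(a_others, b_others)

    def test_one_year_rate_variance_matches_presets(self, full_design):
        """Empirical Var of 1-year rates ~ sigma2_b + within aggregate (~0.66)."""
        vol, _ = default_presets("brain", "AD")
        design = StudyDesign(
            visit_weeks=(0, 52), repeat_scan_visits=(1,), n_cases=10000,
            n_controls=1,
        )
        att = {s: (1, 2) for s, _ in make_subjects(design)}
        df = simulate_volume_dataset(design, {"AD": vol, "control": vol}, att, seed=11)
        ad = df[df["group"] == "AD"]
        y0 = ad[(ad["visit"] == 1) & (ad["scan"] == 1)].set_index("subject")["y"]
        y1 = ad[ad["visit"] == 2].set_index("subject")["y"]
        dt = 52 * 7 / 365.25
        rates = (y1 - y0.loc[y1.index]) / dt
        expected = vol.sigma2_b + (2 * vol.sigma2_d + 2 * vol.sigma2_e) / dt**2
        se = expected * math.sqrt(2 / (len(rates) - 1))
        assert abs(np.var(rates, ddof=1) - expected) < 3 * se
        assert expected == pytest.approx(0.66, rel=0.01)


class TestDirectSimulation:
    def test_same_day_pair_without_scan_noise_is_zero(self, full_design):
        params = DirectModelParams(
            beta=-2.0, sigma2_b=1.0, sigma2_u=0.5, sigma2_v=0.0, sigma2_w=0.0
        )
        df = simulate_direct_dataset(
            full_design, {"AD": params, "control": params}, seed=5
        )
        same_day = df[df["start_visit"] == df["end_visit"]]
        assert len(same_day) > 0
        assert np.allclose(same_day["change"], 0.0, atol=1e-12)

    def test_symmetric_technique_backward_is_negated_forward(
        self, brain_changes
    ):
        fwd = brain_changes[brain_changes["direction"] == "forward"]
        bwd = brain_changes[brain_changes["direction"] == "backward"]
        key = ["subject", "structure"]
        m = fwd.merge(
            bwd,
            left_on=key + ["start_visit", "start_scan", "end_visit", "end_scan"],
            right_on=key + ["end_visit", "end_scan", "start_visit", "start_scan"],
        )
        assert len(m) == len(fwd)
        assert np.allclose(m["change_x"], -m["change_y"], atol=1e-12)

    def test_asymmetry_noise_breaks_negation(self, full_design):
        params = DirectModelParams(
            beta=-2.0, sigma2_b=0.5, sigma2_u=0.1, sigma2_v=0.1, sigma2_w=0.05,
            symmetry_noise_sd=0.3,
        )
        df = simulate_direct_dataset(
            full_design, {"AD": params, "control": params}, seed=5
        )
        fwd = df[df["direction"] == "forward"]["change"].to_numpy()
        bwd = df[df["direction"] == "backward"]["change"].to_numpy()
        assert not np.allclose(fwd, -bwd)

    def test_additivity_defect_variance_is_three_w(self, full_design):
        """Var[c(b->r12) - c(b->r6) - c(r6->r12)] = 3*sigma2_w."""
        params = DirectModelParams(
            beta=-2.0, sigma2_b=0.5, sigma2_u=0.2, sigma2_v=0.1, sigma2_w=0.3
        )
        design = StudyDesign(
            visit_weeks=(0, 26, 52), repeat_scan_visits=(1,), n_cases=8000,
            n_controls=1,
        )
        att = {s: (1, 2, 3) for s, _ in make_subjects(design)}
        df = simulate_direct_dataset(
            design, {"AD": params, "control": params}, att, seed=17
        )
        fwd = df[(df["direction"] == "forward") & (df["group"] == "AD")
                 & (df["start_scan"] == 1)]

        def series(sv, ev):
            sel = fwd[(fwd["start_visit"] == sv) & (fwd["end_visit"] == ev)]
            return sel.set_index("subject")["change"]

        defect = series(1, 3) - series(1, 2) - series(2, 3)
        expected = 3 * params.sigma2_w
        se = expected * math.sqrt(2 / (len(defect) - 1))
        assert abs(np.var(defect, ddof=1) - expected) < 3 * se

    def test_percent_change_kind_roundtrip(self, full_design, brain_params):
        a = simulate_direct_dataset(full_design, brain_params[1], seed=9)
        b = simulate_direct_dataset(
            full_design, brain_params[1], seed=9, change_kind="percent"
        )
        back = 100.0 * np.log1p(b["change"] / 100.0)
        assert np.allclose(back, a["change"], atol=1e-10)


class TestPresets:
    def test_brain_volume_components(self):
        vol, _ = default_presets("brain", "AD")
        assert vol.sigma2_b == pytest.approx(0.47)
        assert vol.within_aggregate == pytest.approx(0.19)

    def test_ventricle_direct_components(self):
        _, direct = default_presets("ventricle", "AD")
        assert direct.sigma2_b == pytest.approx(3.18)
        assert direct.within_aggregate == pytest.approx(0.82)

    @pytest.mark.parametrize("structure", ["brain", "ventricle", "hippo_l", "hippo_r"])
    def test_control_rates_smaller_than_ad(self, structure):
        ad_v, ad_d = default_presets(structure, "AD")
        c_v, c_d = default_presets(structure, "control")
        assert abs(c_v.beta) < abs(ad_v.beta)
        assert abs(c_d.beta) < abs(ad_d.beta)

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError):
            default_presets("amygdala", "AD")

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            VolumeModelParams(beta=0, sigma2_b=-1, sigma2_d=0, sigma2_e=0)
        with pytest.raises(ValueError):
            DirectModelParams(beta=0, sigma2_b=0, sigma2_u=0, sigma2_v=-2, sigma2_w=0)


class TestAttendance:
    def test_default_attendance_pattern(self, full_design):
        att = default_attendance(full_design)
        core = (1, 2, 3, 4, 5, 6, 7)
        full = tuple(range(1, 10))
        lengths = {len(v) for v in att.values()}
        assert lengths == {len(core), len(full)}
        n_full = sum(1 for v in att.values() if len(v) == len(full))
        assert n_full == pytest.approx(len(att) / 2, abs=1)
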