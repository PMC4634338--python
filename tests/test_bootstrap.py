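"""Stratified BCa bootstrap and head-to-head comparisons."""

import numpy as np
import pandas as pd
import pytest

from atrophystats.bootstrap import (
    BootstrapSpec,
    EffectSizePipeline,
    bca_interval,
    bootstrap_effect_size_ci,
    head_to_head,
)
from atrophystats.power import required_sample_size
from atrophystats.synthetic import (
    VolumeModelParams,
    simulate_volume_dataset,
)

from conftest import full_attendance


@pytest.fixture(scope="module")
def small_volume_dataset(small_design):
    params = {
        "AD": VolumeModelParams(beta=-2.0, sigma2_b=0.5, sigma2_d=0.06, sigma2_e=0.04),
        "control": VolumeModelParams(
            beta=-0.5, sigma2_b=0.12, sigma2_d=0.06, sigma2_e=0.04
        ),
    }
    return simulate_volume_dataset(
        small_design, params, full_attendance(small_design), seed=55
    )


class TestBcaInterval:
    def test_reduces_to_percentile_without_corrections(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        lo, hi = bca_interval(x, z0=0.0, accel=0.0)
        assert lo == pytest.approx(np.quantile(x, 0.025))
        assert hi == pytest.approx(np.quantile(x, 0.975))

    def test_positive_bias_correction_shifts_upward(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1000)
        lo0, hi0 = bca_interval(x, 0.0, 0.0)
        lo1, hi1 = bca_interval(x, 0.5, 0.0)
        assert lo1 > lo0 and hi1 > hi0


class TestEffectSizeBootstrap:
    SPEC = BootstrapSpec(n_resamples=60, seed=9)

    def test_deterministic_given_seed(self, small_volume_dataset):
        pipe = EffectSizePipeline(model="volume", followup_years=1.0)
        a = bootstrap_effect_size_ci(small_volume_dataset, pipe, self.SPEC)
        b = bootstrap_effect_size_ci(small_volume_dataset, pipe, self.SPEC)
        assert a == b

    def test_interval_brackets_point_estimate(self, small_volume_dataset):
        pipe = EffectSizePipeline(model="volume", followup_years=1.0)
        res = bootstrap_effect_size_ci(small_volume_dataset, pipe, self.SPEC)
        assert res.es_ci[0] <= res.es_hat <= res.es_ci[1]
        assert res.n_failed == 0

    def test_n_interval_is_monotone_image_of_es_interval(
        self, small_volume_dataset
    ):
        pipe = EffectSizePipeline(model="volume", followup_years=1.0)
        res = bootstrap_effect_size_ci(small_volume_dataset, pipe, self.SPEC)
        lo_abs, hi_abs = sorted(abs(e) for e in res.es_ci)
        assert res.n_total_ci[0] == required_sample_size(hi_abs)[1]
        assert res.n_total_ci[1] == required_sample_size(lo_abs)[1]
        assert res.n_total_ci[0] <= res.n_total_hat <= res.n_total_ci[1]

    def test_identical_subjects_collapse_interval(self, small_design):
        """A cohort of cloned subjects has no sampling variability at all."""
        rng = np.random.default_rng(3)
        rows = []
        scans = [(j, k) for j in range(1, 5) for k in (1, 2) if k == 1 or j == 1]
        noise = {s: rng.normal(0, 0.1) for s in scans}
        for group, beta, n in (("AD", -2.0, 5), ("control", -0.5, 3)):
            for i in range(n):
                for j, k in scans:
                    t = small_design.visit_time_years(j)
                    rows.append(
                        (f"{group}{i}", group, j, k, t, beta * t + noise[(j, k)])
                    )
        df = pd.DataFrame(
            rows, columns=["subject", "group", "visit", "scan", "time_years", "y"]
        )
        pipe = EffectSizePipeline(model="volume", followup_years=1.0)
        res = bootstrap_effect_size_ci(
            df, pipe, BootstrapSpec(n_resamples=25, seed=1)
        )
        assert res.es_ci[0] == pytest.approx(res.es_hat)
        assert res.es_ci[1] == pytest.approx(res.es_hat)
        assert res.z0 == 0.0 and res.accel == 0.0


def _second_technique(dataset, extra_noise_sd, seed):
    """Same subjects re-measured with extra independent scan noise."""
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    out["y"] = out["y"] + rng.normal(0, extra_noise_sd, len(out))
    if "volume" in out.columns:
        out["volume"] = np.exp(out["y"] / 100.0)
    return out


class TestHeadToHead:
    SPEC = BootstrapSpec(n_resamples=80, seed=21)

    def test_self_comparison_is_never_significant(self, small_volume_dataset):
        pipe = EffectSizePipeline(model="volume", followup_years=1.0)
        res = head_to_head(
            small_volume_dataset, small_volume_dataset, pipe, self.SPEC
        )
        assert res.fraction_favoring_a == 0.5
        assert not res.significant

    def test_swapping_complements_fraction(self, small_volume_dataset):
        noisy = _second_technique(small_volume_dataset, 0.6, seed=5)
        pipe = EffectSizePipeline(model="volume", followup_years=1.0)
        ab = head_to_head(small_volume_dataset, noisy, pipe, self.SPEC)
        ba = head_to_head(noisy, small_volume_dataset, pipe, self.SPEC)
        assert ab.fraction_favoring_a == pytest.approx(
            1.0 - ba.fraction_favoring_a
        )

    def test_much_noisier_technique_loses(self, full_design, brain_params):
        """A 4x within-noise competitor is significantly worse."""
        clean = simulate_volume_dataset(
            full_design, brain_params[0], seed=77
        )
        # quadruple within-subject variance: add noise of 3x the e+d level
        within_sd = np.sqrt(
            3 * (brain_params[0]["AD"].sigma2_d + brain_params[0]["AD"].sigma2_e)
        )
        noisy = _second_technique(clean, within_sd, seed=78)
        pipe = EffectSizePipeline(model="volume", followup_years=1.0)
        res = head_to_head(
            clean, noisy, pipe, BootstrapSpec(n_resamples=120, seed=13)
        )
        assert res.fraction_favoring_a > 0.975
        assert res.significant

    def test_subject_mismatch_rejected(self, small_volume_dataset):
        other = small_volume_dataset[
            small_volume_dataset["subject"] != "AD001"
        ]
        pipe = EffectSizePipeline(model="volume")
        with pytest.raises(ValueError):
            head_to_head(small_volume_dataset, other, pipe, self.SPEC)


class TestSpecValidation:
    def test_resample_count_positive(self):
        with pytest.raises(ValueError):
            BootstrapSpec(n_resamples=0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            EffectSizePipeline(model="anova")
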