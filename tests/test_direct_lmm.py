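"""Direct-change mixed model: covariance builder, oracle, identifiability."""

import numpy as np
import pytest

from atrophystats import StudyDesign
from atrophystats.direct_model import (
    DirectModelFit,
    PairDesignRow,
    build_pair_covariance,
    fit_direct_blocks,
    fit_direct_model,
    predict_rate_variance_direct,
    prepare_direct_blocks,
    restricted_loglik,
)
from atrophystats.synthetic import (
    DirectModelParams,
    make_subjects,
    simulate_direct_dataset,
)

from conftest import direct_reml_oracle, full_attendance

PARAMS = DirectModelParams(
    beta=-2.0, sigma2_b=1.0, sigma2_u=0.3, sigma2_v=0.1, sigma2_w=0.05
)


class TestPairCovarianceBuilder:
    def test_single_pair_variance(self):
        row = PairDesignRow(
            delta_t=1.0, visit_signs={1: -1, 2: 1},
            scan_signs={(1, 1): -1, (2, 1): 1},
        )
        cov = build_pair_covariance([row], PARAMS)
        # dt^2*b + 2u + 2v + w = 1 + 0.6 + 0.2 + 0.05
        assert cov[0, 0] == pytest.approx(1.85)

    def test_chained_pairs_share_visit_with_opposite_roles(self):
        r1 = PairDesignRow(1.0, {1: -1, 2: 1}, {(1, 1): -1, (2, 1): 1})
        r2 = PairDesignRow(1.0, {2: -1, 3: 1}, {(2, 1): -1, (3, 1): 1})
        cov = build_pair_covariance([r1, r2], PARAMS)
        # sigma2_b - sigma2_u (shared visit 2, opposite sign) - sigma2_v
        # (shared scan (2,1), also opposite sign)
        assert cov[0, 1] == pytest.approx(1.0 - 0.3 - 0.1)
        assert cov[0, 1] == cov[1, 0]

    def test_same_day_pair_loses_visit_term(self):
        row = PairDesignRow(0.0, {1: 0}, {(1, 1): -1, (1, 2): 1})
        cov = build_pair_covariance([row], PARAMS)
        assert cov[0, 0] == pytest.approx(2 * 0.1 + 0.05)

    def test_psd_on_full_schedule(self, full_design):
        df = simulate_direct_dataset(
            full_design, {"AD": PARAMS, "control": PARAMS}, seed=1
        )
        block = prepare_direct_blocks(df[df["group"] == "AD"])[0]
        rows = []
        for p in range(block.dt.size):
            visit_signs = {
                j + 1: int(s) for j, s in enumerate(block.U[p]) if s != 0
            }
            scan_signs = {
                k: int(s) for k, s in enumerate(block.V[p]) if s != 0
            }
            rows.append(PairDesignRow(block.dt[p], visit_signs or {0: 0}, scan_signs))
        cov = build_pair_covariance(rows, PARAMS)
        eig = np.linalg.eigvalsh(cov)
        assert eig.min() > 0

    def test_malformed_rows_rejected(self):
        with pytest.raises(ValueError):
            PairDesignRow(1.0, {1: -1, 2: 1}, {(1, 1): 1, (2, 1): 1})
        with pytest.raises(ValueError):
            PairDesignRow(1.0, {1: 1, 2: 1}, {(1, 1): -1, (2, 1): 1})


class TestCovarianceAgainstSimulation:
    def test_empirical_cross_pair_covariances(self):
        """Simulated pair covariances match the builder within 3 SEs."""
        design = StudyDesign(
            visit_weeks=(0, 26, 52), repeat_scan_visits=(1,), n_cases=8000,
            n_controls=1,
        )
        att = {s: (1, 2, 3) for s, _ in make_subjects(design)}
        df = simulate_direct_dataset(
            design, {"AD": PARAMS, "control": PARAMS}, att, seed=23
        )
        blocks = prepare_direct_blocks(df[df["group"] == "AD"])
        C = np.column_stack([b.c for b in blocks])
        n = C.shape[1]
        emp = np.cov(C)
        ref = blocks[0]
        from atrophystats.direct_model import _PairPattern

        pat = _PairPattern(ref, [ref.c])
        theory = (
            PARAMS.sigma2_b * pat.DD + PARAMS.sigma2_u * pat.MU
            + PARAMS.sigma2_v * pat.MV + PARAMS.sigma2_w * pat.I
        )
        # SE of a sample covariance ~ sqrt((v_ii v_jj + v_ij^2)/n)
        for i in range(emp.shape[0]):
            for j in range(emp.shape[1]):
                se = np.sqrt(
                    (theory[i, i] * theory[j, j] + theory[i, j] ** 2) / n
                )
                assert abs(emp[i, j] - theory[i, j]) < 3.5 * se


@pytest.fixture(scope="module")
def tiny_direct_dataset():
    design = StudyDesign(
        visit_weeks=(0, 6, 26, 52), repeat_scan_visits=(1, 2), n_cases=4,
        n_controls=2,
    )
    df = simulate_direct_dataset(
        design, {"AD": PARAMS, "control": PARAMS}, full_attendance(design),
        seed=37,
    )
    return df[df["group"] == "AD"]


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "theta",
        [
            (1.0, 0.3, 0.1, 0.05),
            (0.2, 0.05, 0.5, 0.4),
            (2.0, 0.01, 0.02, 0.9),
        ],
    )
    def test_criterion_matches_dense_contrast_density(
        self, tiny_direct_dataset, theta
    ):
        ours = restricted_loglik(tiny_direct_dataset, theta)
        dense = direct_reml_oracle(tiny_direct_dataset, theta)
        assert ours == pytest.approx(dense, abs=1e-6)


class TestFitting:
    def test_slope_only_data_recovered(self, full_design):
        params = DirectModelParams(
            beta=-2.0, sigma2_b=0.5, sigma2_u=0.0, sigma2_v=0.0, sigma2_w=0.0
        )
        df = simulate_direct_dataset(
            full_design, {"AD": params, "control": params}, seed=3
        )
        fit = fit_direct_model(df[df["group"] == "AD"])
        assert fit.beta_hat == pytest.approx(-2.0, abs=0.5)
        assert fit.sigma2_u_hat == 0.0
        assert fit.sigma2_v_hat == 0.0
        assert fit.sigma2_w_hat == 0.0

    def test_single_dataset_estimates_near_truth(self, brain_changes, brain_params):
        truth = brain_params[1]["AD"]
        fit = fit_direct_model(brain_changes[brain_changes["group"] == "AD"])
        assert fit.converged
        assert fit.beta_hat == pytest.approx(truth.beta, abs=4 * fit.se_beta)
        assert fit.within_aggregate == pytest.approx(
            truth.within_aggregate, rel=0.5
        )

    def test_visit_effect_identifiable_by_lrt(self, full_design):
        """LRT rejects sigma2_u = 0 in most replicates when it is truly > 0."""
        params = DirectModelParams(
            beta=-2.0, sigma2_b=0.5, sigma2_u=0.15, sigma2_v=0.05, sigma2_w=0.05
        )
        design = StudyDesign(
            visit_weeks=full_design.visit_weeks, n_cases=100, n_controls=2
        )
        att = {
            s: tuple(range(1, design.n_visits + 1))
            for s, _ in make_subjects(design)
        }
        rejections = 0
        reps = 12
        for rep in range(reps):
            df = simulate_direct_dataset(
                design, {"AD": params, "control": params}, att, seed=400 + rep
            )
            blocks = prepare_direct_blocks(df[df["group"] == "AD"])
            full = fit_direct_blocks(blocks)
            null = fit_direct_blocks(blocks, fix=("u",))
            lrt = 2 * (full.restricted_loglik - null.restricted_loglik)
            # 5% critical value for the 0.5*chi2_0 + 0.5*chi2_1 boundary mix
            rejections += lrt > 2.706
        assert rejections / reps > 0.8

    def test_rank_deficient_rejected(self, tiny_direct_dataset):
        from atrophystats._reml import RemlError

        same_day = tiny_direct_dataset[
            tiny_direct_dataset["start_visit"] == tiny_direct_dataset["end_visit"]
        ]
        with pytest.raises(RemlError):
            fit_direct_model(same_day)


class TestPredictedVariance:
    FIT = DirectModelFit(
        beta_hat=-2.0, se_beta=0.1, sigma2_b_hat=1.0, sigma2_u_hat=0.3,
        sigma2_v_hat=0.1, sigma2_w_hat=0.05,
    )

    def test_rate_variance_example(self):
        assert predict_rate_variance_direct(self.FIT, 1.0) == pytest.approx(1.85)

    def test_asymptote_is_between_subject_variance(self):
        assert predict_rate_variance_direct(self.FIT, 1e6) == pytest.approx(
            1.0, rel=1e-6
        )

    def test_halving_interval_quadruples_within_part(self):
        within = lambda dt: predict_rate_variance_direct(self.FIT, dt) - 1.0
        assert within(0.5) == pytest.approx(4 * within(1.0))

    def test_zero_dt_rejected(self):
        with pytest.raises(ValueError):
            predict_rate_variance_direct(self.FIT, 0.0)
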