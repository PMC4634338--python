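"""BCa bootstrap uncertainty for sample sizes and technique comparisons.

Subjects are the resampling unit, drawn with replacement *within*
disease group so every resample keeps the original number of cases and
controls.  Confidence intervals are computed on the effect-size scale
(whose bootstrap distribution is far more symmetric than that of the
sample size) using the non-parametric bias-corrected and accelerated
(BCa) construction: bias correction ``z0`` from the fraction of
resampled estimates below the point estimate, acceleration ``a`` from a
leave-one-subject-out jackknife.  The interval endpoints are then
mapped through the (monotone in |ES|) sample-size formula, so the lower
|ES| bound yields the upper N bound.

If model fitting fails on more than a set fraction of resamples
(default 1%), the control-group model is refit in its constrained form
(between-subject and visit variances pinned to zero) and the whole
bootstrap is re-run — mirroring standard practice when variance
components near zero derail convergence.

Head-to-head comparisons between two techniques measured on the same
subjects share the resample indices (same seed), so per-resample
effect-size differences are paired; a difference is declared
significant at the 5% level when more than 97.5% of resamples favor one
technique.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import direct_model, volume_model
from .power import effect_size, required_sample_size, sample_size_unrounded


@dataclass(frozen=True)
class BootstrapSpec:
    """Resampling configuration."""

    n_resamples: int = 2000
    seed: int = 0
    fallback_threshold: float = 0.01

    def __post_init__(self):
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


@dataclass
class EffectSizeCI:
    """Point estimate and BCa interval on the effect-size and N scales."""

    es_hat: float
    es_ci: tuple[float, float]
    n_total_hat: int
    n_total_ci: tuple[int, int]
    z0: float
    accel: float
    n_resamples: int
    n_failed: int
    fallback_used: bool = False
    n_sign_flips: int = 0
    followup_years: float = 1.0


@dataclass(frozen=True)
class HeadToHeadResult:
    """Paired bootstrap comparison of two techniques."""

    technique_a: str
    technique_b: str
    structure: str
    followup_years: float
    fraction_favoring_a: float
    significant: bool
    n_resamples: int
    n_failed: int = 0


class PipelineError(RuntimeError):
    pass


class EffectSizePipeline:
    """Fit-plus-power closure: dataset -> effect size at one follow-up.

    ``model`` selects the analysis route: ``"volume"`` fits the
    repeated-volume mixed model, ``"direct"`` the direct-change model.
    The closure caches full-data variance estimates as warm starts so
    the thousands of resample fits converge in a few iterations.
    """

    def __init__(
        self,
        model: str = "volume",
        followup_years: float = 1.0,
        treatment_fraction: float = 0.25,
        power: float = 0.80,
        alpha: float = 0.05,
        exact_quantiles: bool = False,
        case_group: str = "AD",
        control_group: str = "control",
    ):
        if model not in ("volume", "direct"):
            raise ValueError("model must be 'volume' or 'direct'")
        self.model = model
        self.followup_years = followup_years
        self.treatment_fraction = treatment_fraction
        self.power = power
        self.alpha = alpha
        self.exact_quantiles = exact_quantiles
        self.case_group = case_group
        self.control_group = control_group
        mod = volume_model if model == "volume" else direct_model
        self._prepare = (
            mod.prepare_volume_blocks if model == "volume" else mod.prepare_direct_blocks
        )
        self._fit = (
            mod.fit_volume_blocks if model == "volume" else mod.fit_direct_blocks
        )
        self._var_rate = (
            volume_model.predict_rate_variance
            if model == "volume"
            else direct_model.predict_rate_variance_direct
        )

    def prepare(self, dataset: pd.DataFrame) -> tuple[list, list]:
        """Per-subject blocks for (cases, controls)."""
        case = self._prepare(dataset[dataset["group"] == self.case_group])
        ctrl = self._prepare(dataset[dataset["group"] == self.control_group])
        if not case or not ctrl:
            raise PipelineError("dataset must contain both groups")
        return case, ctrl

    def fit_blocks(self, blocks, start=None, multi_start=True, constrained=False):
        return self._fit(
            blocks, constrain_between=constrained, start=start,
            multi_start=multi_start,
        )

    @staticmethod
    def theta(fit) -> np.ndarray:
        if hasattr(fit, "sigma2_d_hat"):
            comps = (fit.sigma2_b_hat, fit.sigma2_d_hat, fit.sigma2_e_hat)
        else:
            comps = (
                fit.sigma2_b_hat, fit.sigma2_u_hat, fit.sigma2_v_hat,
                fit.sigma2_w_hat,
            )
        # floor keeps warm starts strictly inside the log-parameter box
        return np.maximum(np.asarray(comps, dtype=float), 1e-6)

    def es_from_fits(self, case_fit, control_fit) -> float:
        var = self._var_rate(case_fit, self.followup_years)
        if not (var > 0 and np.isfinite(var)):
            raise PipelineError("non-positive case rate variance")
        return effect_size(case_fit.beta_hat, control_fit.beta_hat, var)

    def n_total(self, es: float) -> int:
        return required_sample_size(
            es, self.treatment_fraction, self.power, self.alpha,
            self.exact_quantiles,
        )[1]

    def n_unrounded(self, es: float) -> float:
        return sample_size_unrounded(
            es, self.treatment_fraction, self.power, self.alpha,
            self.exact_quantiles,
        )


def bca_interval(values, z0: float, accel: float, level: float = 0.95):
    """BCa percentile interval of a bootstrap sample.

    With ``z0 = accel = 0`` this reduces exactly to the ordinary
    percentile interval.
    """
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("no bootstrap values")
    alpha = 1.0 - level
    out = []
    for a_level in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = stats.norm.ppf(a_level)
        adj = z0 + (z0 + z) / (1.0 - accel * (z0 + z))
        out.append(float(np.quantile(values, stats.norm.cdf(adj))))
    return tuple(out)


def _safe_es(pipeline, case_blocks, ctrl_blocks, warm_case, warm_ctrl, ctrl_constrained):
    """Effect size from warm-started fits; NaN signals a failed resample."""
    try:
        cf = pipeline.fit_blocks(case_blocks, start=warm_case, multi_start=False)
        gf = pipeline.fit_blocks(
            ctrl_blocks, start=warm_ctrl, multi_start=False,
            constrained=ctrl_constrained,
        )
        if not (cf.converged and gf.converged):
            return np.nan
        es = pipeline.es_from_fits(cf, gf)
        return es if np.isfinite(es) else np.nan
    except Exception:
        return np.nan


def _resample_indices(rng, n_case, n_ctrl, n_resamples):
    idx_case = rng.integers(0, n_case, size=(n_resamples, n_case))
    idx_ctrl = rng.integers(0, n_ctrl, size=(n_resamples, n_ctrl))
    return idx_case, idx_ctrl


def _jackknife_es(pipeline, case_blocks, ctrl_blocks, case_fit, ctrl_fit,
                  warm_case, warm_ctrl, ctrl_constrained):
    """Leave-one-subject-out effect sizes (the bootstrap's acceleration)."""
    es_jack = []
    es_with_full_ctrl = pipeline.es_from_fits  # alias
    for i in range(len(case_blocks)):
        sub = case_blocks[:i] + case_blocks[i + 1:]
        try:
            cf = pipeline.fit_blocks(sub, start=warm_case, multi_start=False)
            es_jack.append(es_with_full_ctrl(cf, ctrl_fit))
        except Exception:
            es_jack.append(np.nan)
    for i in range(len(ctrl_blocks)):
        sub = ctrl_blocks[:i] + ctrl_blocks[i + 1:]
        try:
            gf = pipeline.fit_blocks(
                sub, start=warm_ctrl, multi_start=False,
                constrained=ctrl_constrained,
            )
            es_jack.append(es_with_full_ctrl(case_fit, gf))
        except Exception:
            es_jack.append(np.nan)
    return np.asarray(es_jack, dtype=float)


def _acceleration(es_jack: np.ndarray) -> float:
    es_jack = es_jack[np.isfinite(es_jack)]
    if es_jack.size < 3:
        return 0.0
    d = es_jack.mean() - es_jack
    denom = float(np.sum(d * d)) ** 1.5
    if denom <= 0:
        return 0.0
    return float(np.sum(d**3) / (6.0 * denom))


def bootstrap_effect_size_ci(
    dataset: pd.DataFrame,
    pipeline: EffectSizePipeline,
    spec: BootstrapSpec = BootstrapSpec(),
) -> EffectSizeCI:
    """Stratified subject bootstrap of the effect size with a BCa interval.

    Returns the point estimate, the 95% BCa interval on the effect-size
    scale, and the corresponding total-sample-size interval obtained by
    mapping the |ES| endpoints through the sample-size formula.
    """
    case_blocks, ctrl_blocks = pipeline.prepare(dataset)
    return _bootstrap_from_blocks(pipeline, spec, case_blocks, ctrl_blocks)


def _bootstrap_from_blocks(
    pipeline, spec, case_blocks, ctrl_blocks, ctrl_constrained=False
) -> EffectSizeCI:
    case_fit = pipeline.fit_blocks(case_blocks, multi_start=True)
    ctrl_fit = pipeline.fit_blocks(
        ctrl_blocks, multi_start=True, constrained=ctrl_constrained
    )
    if not (case_fit.converged and ctrl_fit.converged):
        raise PipelineError("full-data model fit did not converge")
    es_hat = pipeline.es_from_fits(case_fit, ctrl_fit)
    warm_case = pipeline.theta(case_fit)
    warm_ctrl = pipeline.theta(ctrl_fit)

    rng = np.random.default_rng(spec.seed)
    idx_case, idx_ctrl = _resample_indices(
        rng, len(case_blocks), len(ctrl_blocks), spec.n_resamples
    )
    es_star = np.empty(spec.n_resamples)
    for r in range(spec.n_resamples):
        cb = [case_blocks[i] for i in idx_case[r]]
        gb = [ctrl_blocks[i] for i in idx_ctrl[r]]
        es_star[r] = _safe_es(
            pipeline, cb, gb, warm_case, warm_ctrl, ctrl_constrained
        )

    failed = ~np.isfinite(es_star)
    n_failed = int(failed.sum())
    if (
        n_failed / spec.n_resamples > spec.fallback_threshold
        and not ctrl_constrained
    ):
        result = _bootstrap_from_blocks(
            pipeline, spec, case_blocks, ctrl_blocks, ctrl_constrained=True
        )
        result.fallback_used = True
        return result

    es_ok = es_star[~failed]
    if es_ok.size == 0:
        raise PipelineError("every bootstrap resample failed")

    # Bias correction: fraction of resamples below the point estimate,
    # clipped away from 0/1 so the normal quantile stays finite.
    frac_below = np.clip(
        np.mean(es_ok < es_hat), 1.0 / (es_ok.size + 1), es_ok.size / (es_ok.size + 1)
    )
    z0 = float(stats.norm.ppf(frac_below))
    es_jack = _jackknife_es(
        pipeline, case_blocks, ctrl_blocks, case_fit, ctrl_fit,
        warm_case, warm_ctrl, ctrl_constrained,
    )
    accel = _acceleration(es_jack)
    if np.allclose(es_ok, es_ok[0]):
        # Degenerate bootstrap distribution: interval collapses.
        es_ci = (float(es_ok[0]), float(es_ok[0]))
        z0 = 0.0
        accel = 0.0
    else:
        es_ci = bca_interval(es_ok, z0, accel)

    n_sign_flips = int(np.sum(np.sign(es_ok) != np.sign(es_hat)))
    # N interval: map |ES| endpoints; smaller |ES| -> larger N.
    abs_bounds = sorted(abs(b) for b in es_ci)
    n_hi = pipeline.n_total(max(abs_bounds[0], 1e-12))
    n_lo = pipeline.n_total(abs_bounds[1])
    return EffectSizeCI(
        es_hat=float(es_hat),
        es_ci=(float(es_ci[0]), float(es_ci[1])),
        n_total_hat=pipeline.n_total(es_hat),
        n_total_ci=(n_lo, n_hi),
        z0=z0,
        accel=accel,
        n_resamples=spec.n_resamples,
        n_failed=n_failed,
        fallback_used=ctrl_constrained,
        n_sign_flips=n_sign_flips,
        followup_years=pipeline.followup_years,
    )


def head_to_head(
    dataset_a: pd.DataFrame,
    dataset_b: pd.DataFrame,
    pipeline: EffectSizePipeline,
    spec: BootstrapSpec = BootstrapSpec(),
    technique_a: str = "A",
    technique_b: str = "B",
    structure: str = "",
) -> HeadToHeadResult:
    """Paired bootstrap comparison of two techniques on the same subjects.

    Both datasets must cover identical subjects; each resample draws one
    subject multiset (per group) applied to both techniques, and the
    comparison counts the fraction of resamples in which technique A's
    |effect size| exceeds B's (i.e., A needs the smaller trial).  Ties
    split evenly, so a technique compared with itself sits at exactly
    0.5 and is never significant.
    """
    subj_a = set(dataset_a["subject"])
    subj_b = set(dataset_b["subject"])
    if subj_a != subj_b:
        raise ValueError("head-to-head datasets must cover identical subjects")

    prepared = []
    for ds in (dataset_a, dataset_b):
        case_blocks, ctrl_blocks = pipeline.prepare(ds)
        case_blocks = sorted(case_blocks, key=lambda b: b.subject)
        ctrl_blocks = sorted(ctrl_blocks, key=lambda b: b.subject)
        case_fit = pipeline.fit_blocks(case_blocks, multi_start=True)
        ctrl_fit = pipeline.fit_blocks(ctrl_blocks, multi_start=True)
        prepared.append(
            (case_blocks, ctrl_blocks, pipeline.theta(case_fit), pipeline.theta(ctrl_fit))
        )
    n_case = len(prepared[0][0])
    n_ctrl = len(prepared[0][1])
    if len(prepared[1][0]) != n_case or len(prepared[1][1]) != n_ctrl:
        raise ValueError("group sizes differ between datasets")

    rng = np.random.default_rng(spec.seed)
    idx_case, idx_ctrl = _resample_indices(rng, n_case, n_ctrl, spec.n_resamples)
    es_pair = np.empty((spec.n_resamples, 2))
    for r in range(spec.n_resamples):
        for s, (cb_all, gb_all, wc, wg) in enumerate(prepared):
            cb = [cb_all[i] for i in idx_case[r]]
            gb = [gb_all[i] for i in idx_ctrl[r]]
            es_pair[r, s] = _safe_es(pipeline, cb, gb, wc, wg, False)

    ok = np.all(np.isfinite(es_pair), axis=1)
    n_failed = int((~ok).sum())
    diffs = np.abs(es_pair[ok, 0]) - np.abs(es_pair[ok, 1])
    if diffs.size == 0:
        raise PipelineError("every paired resample failed")
    frac_a = float((np.sum(diffs > 0) + 0.5 * np.sum(diffs == 0)) / diffs.size)
    return HeadToHeadResult(
        technique_a=technique_a,
        technique_b=technique_b,
        structure=structure,
        followup_years=pipeline.followup_years,
        fraction_favoring_a=frac_a,
        significant=bool(frac_a > 0.975 or frac_a < 0.025),
        n_resamples=spec.n_resamples,
        n_failed=n_failed,
    )
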