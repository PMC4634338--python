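"""Clinical-trial sample sizes from fitted atrophy models.

A hypothetical two-arm, two-visit trial measures each participant's
change over a follow-up of ``t`` years.  The treatment is assumed to
slow the *excess* atrophy rate (case rate minus the healthy-ageing
control rate) by a fraction ``f`` (default 25%) without altering
variability.  With 80% power at a two-sided 5% level, the required
sample size per arm is

    N = 2 * (z_{0.975} + z_{0.80})^2 / (f * ES)^2,
    ES = (beta_case - beta_control) / sqrt(Var(rate_case))

where Var(rate_case) comes from the fitted case-group model evaluated
at the trial's follow-up interval.  By default the printed z-values
1.960 and 0.842 are used so results reproduce the standard formula
literally; ``exact_quantiles=True`` switches to full-precision normal
quantiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .direct_model import DirectModelFit, predict_rate_variance_direct
from .volume_model import predict_rate_variance

#: z-values as conventionally printed for 97.5% / 80%.
Z_ALPHA_PRINTED = 1.960
Z_POWER_PRINTED = 0.842

DEFAULT_FOLLOWUPS = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class TrialPowerResult:
    """Sample-size requirement for one structure/technique/follow-up."""

    structure: str
    technique: str
    followup_years: float
    beta_case: float
    beta_control: float
    var_rate_case: float
    effect_size: float
    n_per_arm: int
    n_total: int


def effect_size(beta_case: float, beta_control: float, var_rate_case: float) -> float:
    """Standardized group difference in mean rate (sign preserved)."""
    if not var_rate_case > 0:
        raise ValueError("var_rate_case must be positive")
    return (beta_case - beta_control) / math.sqrt(var_rate_case)


def _z_values(alpha: float, power: float, exact_quantiles: bool):
    if not exact_quantiles and abs(alpha - 0.05) < 1e-12 and abs(power - 0.80) < 1e-12:
        return Z_ALPHA_PRINTED, Z_POWER_PRINTED
    return float(stats.norm.ppf(1.0 - alpha / 2.0)), float(stats.norm.ppf(power))


def sample_size_unrounded(
    es: float,
    treatment_fraction: float = 0.25,
    power: float = 0.80,
    alpha: float = 0.05,
    exact_quantiles: bool = False,
) -> float:
    """Unrounded per-arm N; the quantity mapped through bootstrap CIs."""
    if es == 0 or not math.isfinite(es):
        raise ValueError("effect size must be nonzero and finite")
    if not 0 < treatment_fraction <= 1:
        raise ValueError("treatment_fraction must be in (0, 1]")
    z_a, z_p = _z_values(alpha, power, exact_quantiles)
    return 2.0 * (z_a + z_p) ** 2 / (treatment_fraction * abs(es)) ** 2


def required_sample_size(
    es: float,
    treatment_fraction: float = 0.25,
    power: float = 0.80,
    alpha: float = 0.05,
    exact_quantiles: bool = False,
) -> tuple[int, int]:
    """(per-arm, total) sample size; per-arm rounded up, total doubled."""
    n = sample_size_unrounded(es, treatment_fraction, power, alpha, exact_quantiles)
    n_arm = int(math.ceil(n - 1e-9))
    return n_arm, 2 * n_arm


def _var_rate(fit, dt: float) -> float:
    if isinstance(fit, DirectModelFit) or hasattr(fit, "sigma2_u_hat"):
        return predict_rate_variance_direct(fit, dt)
    return predict_rate_variance(fit, dt)


def power_table(
    case_fit,
    control_fit,
    followups=DEFAULT_FOLLOWUPS,
    structure: str = "",
    technique: str = "",
    treatment_fraction: float = 0.25,
    power: float = 0.80,
    alpha: float = 0.05,
    exact_quantiles: bool = False,
) -> list[TrialPowerResult]:
    """Sample sizes across follow-up durations from a pair of group fits.

    The variance in the effect-size denominator is the case-group rate
    variance at each follow-up; the control fit contributes only its
    mean rate.
    """
    for fit, label in ((case_fit, "case"), (control_fit, "control")):
        if not getattr(fit, "converged", True):
            raise RuntimeError(f"{label} model fit did not converge")
    rows = []
    for t in followups:
        var = _var_rate(case_fit, t)
        es = effect_size(case_fit.beta_hat, control_fit.beta_hat, var)
        n_arm, n_total = required_sample_size(
            es, treatment_fraction, power, alpha, exact_quantiles
        )
        rows.append(
            TrialPowerResult(
                structure=structure,
                technique=technique,
                followup_years=float(t),
                beta_case=case_fit.beta_hat,
                beta_control=control_fit.beta_hat,
                var_rate_case=var,
                effect_size=es,
                n_per_arm=n_arm,
                n_total=n_total,
            )
        )
    return rows
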