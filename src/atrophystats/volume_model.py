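"""Random-slope mixed model for repeated volume measurements.

The outcome is ``y_ijk = 100*ln(volume)`` of subject ``i`` at visit
``j``, scan ``k``:

    y_ijk = alpha_i + (beta + b_i) * t_ij + d_ij + e_ijk

with fixed subject levels ``alpha_i``, fixed mean rate ``beta`` (%/yr),
random slopes ``b_i ~ N(0, sigma2_b)``, random visit effects
``d_ij ~ N(0, sigma2_d)`` and scan-level residuals
``e_ijk ~ N(0, sigma2_e)``.  Visit effects are identifiable because
some visits carry two back-to-back scans.  Variance components are
estimated by REML (the ~n_subjects fixed intercepts would bias plain
maximum likelihood); ``alpha_i`` and ``beta`` are profiled out by GLS.

Implied variances used downstream:

* change over an interval dt:   dt^2*sigma2_b + 2*sigma2_d + 2*sigma2_e
* rate over an interval dt:     sigma2_b + (2*sigma2_d + 2*sigma2_e)/dt^2

so within-subject noise contributes less the longer the follow-up,
while the between-subject term is irreducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._reml import LOG_2PI, RemlError, inv_from_cholesky, optimize_reml


@dataclass
class VolumeModelFit:
    """REML estimates from the repeated-volume model."""

    beta_hat: float
    se_beta: float
    sigma2_b_hat: float
    sigma2_d_hat: float
    sigma2_e_hat: float
    restricted_loglik: float = np.nan
    converged: bool = True
    boundary: tuple = ()
    constrained: bool = False
    n_subjects: int = 0
    n_obs: int = 0
    alpha_hat: dict = field(default_factory=dict)

    @property
    def within_aggregate(self) -> float:
        """Within-subject variance of a 1-year rate: 2*sigma2_d + 2*sigma2_e."""
        return 2.0 * self.sigma2_d_hat + 2.0 * self.sigma2_e_hat

    def report(self) -> dict:
        return {
            "model": "volume",
            "beta_hat_pct_per_year": self.beta_hat,
            "se_beta": self.se_beta,
            "sigma2_b": self.sigma2_b_hat,
            "sigma2_d": self.sigma2_d_hat,
            "sigma2_e": self.sigma2_e_hat,
            "within_aggregate": self.within_aggregate,
            "restricted_loglik": self.restricted_loglik,
            "converged": self.converged,
            "boundary_components": list(self.boundary),
            "constrained": self.constrained,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
        }


class _SubjectBlock:
    """One subject's times, visit labels and outcomes."""

    __slots__ = ("subject", "t", "visits", "y", "key")

    def __init__(self, subject, t, visits, y):
        self.subject = subject
        self.t = np.asarray(t, dtype=float)
        self.visits = np.asarray(visits)
        self.y = np.asarray(y, dtype=float)
        self.key = (tuple(self.t), tuple(self.visits))


def prepare_volume_blocks(records: pd.DataFrame) -> list[_SubjectBlock]:
    """Split a tidy volumes table into per-subject blocks.

    The outcome is the ``y`` column (100*ln volume) if present, else
    computed from ``volume``.
    """
    df = records
    if "y" in df.columns:
        y_all = df["y"].to_numpy(dtype=float)
    else:
        vol = df["volume"].to_numpy(dtype=float)
        if np.any(vol <= 0):
            raise RemlError("non-positive volume in records")
        y_all = 100.0 * np.log(vol)
    order = np.lexsort(
        (df["scan"].to_numpy(), df["visit"].to_numpy(), df["subject"].to_numpy())
    )
    subj = df["subject"].to_numpy()[order]
    t = df["time_years"].to_numpy(dtype=float)[order]
    visits = df["visit"].to_numpy()[order]
    y = y_all[order]
    blocks = []
    start = 0
    for i in range(1, len(subj) + 1):
        if i == len(subj) or subj[i] != subj[start]:
            blocks.append(
                _SubjectBlock(subj[start], t[start:i], visits[start:i], y[start:i])
            )
            start = i
    return blocks


class _Pattern:
    """Subjects sharing a visit schedule, with outcomes stacked columnwise."""

    __slots__ = ("t", "TT", "M", "I", "Y", "m", "n", "subjects")

    def __init__(self, t, visits, ys, subjects):
        self.t = np.asarray(t, dtype=float)
        self.n = self.t.size
        self.TT = np.outer(self.t, self.t)
        v = np.asarray(visits)
        self.M = (v[:, None] == v[None, :]).astype(float)
        self.I = np.eye(self.n)
        self.Y = np.column_stack(ys)
        self.m = self.Y.shape[1]
        self.subjects = subjects


def _group_patterns(blocks) -> list[_Pattern]:
    groups: dict = {}
    for b in blocks:
        groups.setdefault(b.key, []).append(b)
    out = []
    for key, members in groups.items():
        out.append(
            _Pattern(
                members[0].t,
                members[0].visits,
                [b.y for b in members],
                [b.subject for b in members],
            )
        )
    return out


def _volume_moment_start(blocks) -> np.ndarray:
    """Rough method-of-moments start: per-subject OLS slopes and residuals."""
    slopes, resid_vars = [], []
    for b in blocks:
        t, y = b.t, b.y
        if np.ptp(t) <= 0 or t.size < 3:
            continue
        A = np.column_stack([np.ones_like(t), t])
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        slopes.append(coef[1])
        dof = t.size - 2
        if dof > 0 and res.size:
            resid_vars.append(res[0] / dof)
    rv = float(np.mean(resid_vars)) if resid_vars else 1.0
    sb = float(np.var(slopes)) if len(slopes) > 1 else 1.0
    rv = max(rv, 1e-4)
    sb = max(sb * 0.5, 1e-4)
    return np.array([sb, 0.6 * rv, 0.4 * rv])


def _setup(blocks):
    n_subjects = len(blocks)
    if n_subjects < 2:
        raise RemlError("need at least two subjects")
    all_t = np.concatenate([b.t for b in blocks])
    if np.unique(all_t).size < 2:
        raise RemlError("degenerate data: a single distinct time point")
    patterns = _group_patterns(blocks)
    N = int(sum(p.n * p.m for p in patterns))
    p_fixed = n_subjects + 1
    if N <= p_fixed:
        raise RemlError("fewer observations than fixed effects")

    # log|X'X| pieces: per subject, intercept + common slope column.
    log_xtx = 0.0
    schur0 = 0.0
    for pat in patterns:
        log_xtx += pat.m * np.log(pat.n)
        c0 = float(pat.t @ pat.t)
        b0 = float(pat.t.sum())
        schur0 += pat.m * (c0 - b0 * b0 / pat.n)
    log_xtx += np.log(schur0)
    return patterns, N, p_fixed, log_xtx


def _make_assemble(patterns, N, p_fixed, log_xtx):
    """Criterion/gradient evaluator for one prepared group of subjects."""

    def assemble(theta, want_grad=False):
        s2b, s2d, s2e = theta
        logdet = 0.0
        sum_log_a = 0.0
        S = 0.0
        num = 0.0
        ypy_parts = 0.0
        cache = []
        for pat in patterns:
            sigma = s2b * pat.TT + s2d * pat.M + s2e * pat.I
            W, ld = inv_from_cholesky(sigma)
            if W is None:
                return None
            w1 = W.sum(axis=1)
            wt = W @ pat.t
            WY = W @ pat.Y
            a = float(w1.sum())
            bb = float(pat.t @ w1)
            c = float(pat.t @ wt)
            u = w1 @ pat.Y
            v = wt @ pat.Y
            q = np.einsum("nm,nm->m", pat.Y, WY)
            if a <= 0:
                return None
            logdet += pat.m * ld
            sum_log_a += pat.m * np.log(a)
            S += pat.m * (c - bb * bb / a)
            num += float(np.sum(v - (bb / a) * u))
            ypy_parts += float(np.sum(q - u * u / a))
            cache.append((W, w1, wt, WY, a, bb, c, u))
        if S <= 0:
            return None
        beta = num / S
        ypy = ypy_parts - num * num / S
        neg2 = (
            (N - p_fixed) * LOG_2PI
            + logdet
            + sum_log_a
            + np.log(S)
            - log_xtx
            + ypy
        )
        if not want_grad:
            return neg2, beta, 1.0 / S, cache

        # Analytic gradient: tr(W G_k) - tr(M^-1 X'W G_k W X) - (Wr)'G_k(Wr)
        # with the fixed-effects information M in arrow form (per-subject
        # intercepts bordered by the common slope column).
        tr_term = np.zeros(3)
        arrow = np.zeros(3)  # sum_i p_i/a_i + (g_i^2 p_i - 2 g_i q_i)/S
        h_tot = np.zeros(3)
        r_term = np.zeros(3)
        info = np.zeros((3, 3))
        for pat, (W, w1, wt, WY, a, bb, c, u) in zip(patterns, cache):
            g = bb / a
            WM = W @ pat.M
            Mw1 = pat.M @ w1
            Mwt = pat.M @ wt
            p_k = np.array([bb * bb, float(w1 @ Mw1), float(w1 @ w1)])
            q_k = np.array([bb * c, float(w1 @ Mwt), float(w1 @ wt)])
            h_k = np.array([c * c, float(wt @ Mwt), float(wt @ wt)])
            tr_term += pat.m * np.array(
                [c, float(np.trace(WM)), float(np.trace(W))]
            )
            arrow += pat.m * (p_k / a + (g * g * p_k - 2.0 * g * q_k) / S)
            h_tot += pat.m * h_k
            alpha = (u - bb * beta) / a
            WR = WY - np.outer(w1, alpha) - beta * wt[:, None]
            tWR = pat.t @ WR
            MWR = pat.M @ WR
            r_term += np.array(
                [
                    float(tWR @ tWR),
                    float(np.einsum("nm,nm->", WR, MWR)),
                    float(np.einsum("nm,nm->", WR, WR)),
                ]
            )
            # expected information of the -2*loglik: tr(W G_k W G_l);
            # the slope component is rank one so its row is the h_k sandwich
            info[0] += pat.m * h_k
            info[1, 1] += pat.m * float(np.sum(WM * WM.T))
            info[1, 2] += pat.m * float(np.sum(WM * W))
            info[2, 2] += pat.m * float(np.sum(W * W))
        info[1, 0] = info[0, 1]
        info[2, 0] = info[0, 2]
        info[2, 1] = info[1, 2]
        grad = tr_term - (arrow + h_tot / S) - r_term
        return neg2, beta, 1.0 / S, cache, grad, info

    return assemble


def restricted_loglik(records, theta) -> float:
    """Restricted log-likelihood at fixed variance components.

    ``records`` is a tidy table (or prepared blocks); ``theta`` is
    (sigma2_b, sigma2_d, sigma2_e).  Fixed effects are profiled by GLS.
    Returns -inf for a singular covariance.
    """
    blocks = (
        prepare_volume_blocks(records)
        if isinstance(records, pd.DataFrame)
        else records
    )
    assemble = _make_assemble(*_setup(blocks))
    out = assemble(np.asarray(theta, dtype=float))
    return -np.inf if out is None else -0.5 * out[0]


def fit_volume_blocks(
    blocks,
    constrain_between: bool = False,
    start=None,
    multi_start: bool = True,
    fix: tuple = (),
) -> VolumeModelFit:
    """REML fit of the repeated-volume model on prepared subject blocks.

    ``fix`` names components ('b', 'd', 'e') pinned at zero, e.g. for
    likelihood-ratio tests of a single variance component;
    ``constrain_between`` is shorthand for fixing 'b' and 'd'.
    """
    n_subjects = len(blocks)
    patterns, N, p_fixed, log_xtx = _setup(blocks)
    assemble = _make_assemble(patterns, N, p_fixed, log_xtx)

    def neg2_and_grad(theta):
        out = assemble(theta, want_grad=True)
        if out is None:
            return np.inf, None, None
        return out[0], out[4], out[5]

    if start is None:
        start = _volume_moment_start(blocks)
    start = np.asarray(start, dtype=float)
    starts = [start]
    if multi_start:
        starts += [start / 10.0, start * 10.0]

    pinned = set(fix) | ({"b", "d"} if constrain_between else set())
    if not pinned <= {"b", "d", "e"}:
        raise ValueError(f"unknown component in fix: {sorted(pinned)}")
    free = np.array([name not in pinned for name in "bde"])
    if not free.any():
        raise ValueError("at least one variance component must be free")
    fixed = np.where(free, np.nan, 0.0)
    theta_hat, best, converged, boundary = optimize_reml(
        neg2_and_grad, starts, free, fixed
    )

    # Assemble reported quantities at the (positive) optimum so GLS pieces
    # stay well defined even when components were truncated to zero.
    eval_theta = np.maximum(theta_hat, 1e-12)
    out = assemble(eval_theta)
    if out is None:
        return VolumeModelFit(
            np.nan, np.nan, *theta_hat, restricted_loglik=np.nan,
            converged=False, boundary=boundary, constrained=constrain_between,
            n_subjects=n_subjects, n_obs=N,
        )
    _, beta, var_beta, cache = out
    alphas = {}
    for pat, (W, w1, wt, WY, a, bb, c, u) in zip(patterns, cache):
        vals = (u - bb * beta) / a
        for subj, val in zip(pat.subjects, vals):
            alphas[subj] = float(val)
    return VolumeModelFit(
        beta_hat=float(beta),
        se_beta=float(np.sqrt(var_beta)),
        sigma2_b_hat=float(theta_hat[0]),
        sigma2_d_hat=float(theta_hat[1]),
        sigma2_e_hat=float(theta_hat[2]),
        restricted_loglik=-0.5 * best,
        converged=converged,
        boundary=tuple("bde"[i] for i in boundary),
        constrained=constrain_between,
        n_subjects=n_subjects,
        n_obs=N,
        alpha_hat=alphas,
    )


def fit_volume_model(
    records: pd.DataFrame,
    constrain_between: bool = False,
    start=None,
    multi_start: bool = True,
    fix: tuple = (),
) -> VolumeModelFit:
    """Fit the repeated-volume model to one group/structure's records.

    ``records`` is a tidy table with columns subject, visit, scan,
    time_years and volume (or a precomputed ``y`` = 100*ln volume).
    ``constrain_between`` pins sigma2_b = sigma2_d = 0, the fallback
    used when the unconstrained model fails to converge on resamples.
    """
    blocks = prepare_volume_blocks(records)
    return fit_volume_blocks(
        blocks, constrain_between=constrain_between, start=start,
        multi_start=multi_start, fix=fix,
    )


def _components(fit):
    if hasattr(fit, "sigma2_b_hat"):
        return fit.sigma2_b_hat, fit.sigma2_d_hat, fit.sigma2_e_hat
    return fit.sigma2_b, fit.sigma2_d, fit.sigma2_e


def predict_change_variance(fit, dt: float) -> float:
    """Variance of a measured difference over ``dt`` years."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    s2b, s2d, s2e = _components(fit)
    return dt * dt * s2b + 2.0 * s2d + 2.0 * s2e


def predict_rate_variance(fit, dt: float) -> float:
    """Variance of a rate of change measured over ``dt`` years."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    s2b, s2d, s2e = _components(fit)
    return s2b + (2.0 * s2d + 2.0 * s2e) / (dt * dt)
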