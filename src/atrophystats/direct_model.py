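"""Mixed model for repeated direct measures of change.

Direct change measures (e.g., boundary-shift-integral or registration
based) over the ordered scan pair (j1,k1) -> (j2,k2) of subject ``i``
are modelled on the 100*ln scale as

    c = (beta + b_i)*(t_ij2 - t_ij1) - u_ij1 + u_ij2
        - v_ij1k1 + v_ij2k2 + w

with b_i ~ N(0, sigma2_b), signed visit effects u_ij ~ N(0, sigma2_u),
signed scan effects v_ijk ~ N(0, sigma2_v) and a pair residual
w ~ N(0, sigma2_w) capturing the (small) non-additivity of direct
measures.  A visit or scan effect enters negatively when the pair
starts there and positively when it ends there, so effects shared
between a subject's pairs induce a cross-pair covariance:

    Cov(p, q) = sigma2_b*dt_p*dt_q + sigma2_u*<visit signs>
                + sigma2_v*<scan signs> + sigma2_w*[p == q]

The implied variance of a single measure is
dt^2*sigma2_b + 2*sigma2_u + 2*sigma2_v + sigma2_w (same-day pairs lose
the visit term because the two signs cancel), and of a rate,
sigma2_b + (2*sigma2_u + 2*sigma2_v + sigma2_w)/dt^2.

Only forward measures enter the fit; backward measures are
near-duplicates used by :mod:`atrophystats.reliability` for symmetry.
Estimation is REML with the mean rate ``beta`` profiled out by GLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from ._reml import LOG_2PI, RemlError, inv_from_cholesky, optimize_reml
from .synthetic import DirectModelParams


@dataclass
class DirectModelFit:
    """REML estimates from the repeated direct-change model."""

    beta_hat: float
    se_beta: float
    sigma2_b_hat: float
    sigma2_u_hat: float
    sigma2_v_hat: float
    sigma2_w_hat: float
    restricted_loglik: float = np.nan
    converged: bool = True
    boundary: tuple = ()
    constrained: bool = False
    n_subjects: int = 0
    n_pairs: int = 0

    @property
    def within_aggregate(self) -> float:
        """Within-subject variance of a 1-year rate: 2u + 2v + w."""
        return (
            2.0 * self.sigma2_u_hat + 2.0 * self.sigma2_v_hat + self.sigma2_w_hat
        )

    def report(self) -> dict:
        return {
            "model": "direct",
            "beta_hat_pct_per_year": self.beta_hat,
            "se_beta": self.se_beta,
            "sigma2_b": self.sigma2_b_hat,
            "sigma2_u": self.sigma2_u_hat,
            "sigma2_v": self.sigma2_v_hat,
            "sigma2_w": self.sigma2_w_hat,
            "within_aggregate": self.within_aggregate,
            "restricted_loglik": self.restricted_loglik,
            "converged": self.converged,
            "boundary_components": list(self.boundary),
            "constrained": self.constrained,
            "n_subjects": self.n_subjects,
            "n_pairs": self.n_pairs,
        }


@dataclass(frozen=True)
class PairDesignRow:
    """Design of one pair measurement: interval and signed incidences."""

    delta_t: float
    visit_signs: dict = field(default_factory=dict)
    scan_signs: dict = field(default_factory=dict)

    def __post_init__(self):
        scan_vals = sorted(self.scan_signs.values())
        if scan_vals != [-1, 1]:
            raise ValueError("scan_signs must contain exactly one -1 and one +1")
        if sum(self.visit_signs.values()) != 0:
            raise ValueError("visit_signs must sum to zero")


def build_pair_covariance(rows, params: DirectModelParams) -> np.ndarray:
    """Covariance matrix over one subject's pair measurements."""
    n = len(rows)
    dt = np.array([r.delta_t for r in rows], dtype=float)
    cov = params.sigma2_b * np.outer(dt, dt) + params.sigma2_w * np.eye(n)
    for p in range(n):
        for q in range(n):
            sv = sum(
                s * rows[q].visit_signs.get(j, 0)
                for j, s in rows[p].visit_signs.items()
            )
            ss = sum(
                s * rows[q].scan_signs.get(k, 0)
                for k, s in rows[p].scan_signs.items()
            )
            cov[p, q] += params.sigma2_u * sv + params.sigma2_v * ss
    return cov


class _SubjectPairBlock:
    """One subject's forward pair measurements with signed incidences."""

    __slots__ = ("subject", "dt", "U", "V", "c", "key")

    def __init__(self, subject, starts, ends, dt, c):
        self.subject = subject
        self.dt = np.asarray(dt, dtype=float)
        self.c = np.asarray(c, dtype=float)
        visits = sorted({s[0] for s in starts} | {e[0] for e in ends})
        scans = sorted(set(starts) | set(ends))
        v_ix = {v: i for i, v in enumerate(visits)}
        s_ix = {s: i for i, s in enumerate(scans)}
        n = len(dt)
        U = np.zeros((n, len(visits)))
        V = np.zeros((n, len(scans)))
        for p, (s, e) in enumerate(zip(starts, ends)):
            U[p, v_ix[s[0]]] -= 1.0
            U[p, v_ix[e[0]]] += 1.0
            V[p, s_ix[s]] -= 1.0
            V[p, s_ix[e]] += 1.0
        self.U = U
        self.V = V
        self.key = (tuple(self.dt), tuple(starts), tuple(ends))


def prepare_direct_blocks(records: pd.DataFrame) -> list[_SubjectPairBlock]:
    """Split a tidy changes table (forward rows only) into subject blocks.

    The ``change`` column must already be standardized to the 100*ln
    scale (see :func:`atrophystats.reliability.c_direct` and the readers
    in :mod:`atrophystats.io`).
    """
    df = records
    if "direction" in df.columns:
        df = df[df["direction"] == "forward"]
    if df.empty:
        raise RemlError("no forward change records")
    cols = ["start_visit", "start_scan", "end_visit", "end_scan"]
    order = np.lexsort(tuple(df[c].to_numpy() for c in reversed(cols)) + (df["subject"].to_numpy(),))
    df = df.iloc[order]
    blocks = []
    for subj, g in df.groupby("subject", sort=True):
        starts = list(zip(g["start_visit"].astype(int), g["start_scan"].astype(int)))
        ends = list(zip(g["end_visit"].astype(int), g["end_scan"].astype(int)))
        if len(set(zip(starts, ends))) != len(starts):
            raise RemlError(f"duplicate pair rows for subject {subj}")
        blocks.append(
            _SubjectPairBlock(
                subj, starts, ends,
                g["delta_t_years"].to_numpy(dtype=float),
                g["change"].to_numpy(dtype=float),
            )
        )
    return blocks


class _PairPattern:
    __slots__ = ("dt", "DD", "MU", "MV", "I", "C", "m", "n")

    def __init__(self, block, cs):
        self.dt = block.dt
        self.n = self.dt.size
        self.DD = np.outer(self.dt, self.dt)
        self.MU = block.U @ block.U.T
        self.MV = block.V @ block.V.T
        self.I = np.eye(self.n)
        self.C = np.column_stack(cs)
        self.m = self.C.shape[1]


def _group_pair_patterns(blocks) -> list[_PairPattern]:
    groups: dict = {}
    for b in blocks:
        groups.setdefault(b.key, []).append(b)
    return [_PairPattern(members[0], [b.c for b in members]) for members in groups.values()]


def _direct_moment_start(blocks) -> np.ndarray:
    rates, resid_vars = [], []
    for b in blocks:
        mask = np.abs(b.dt) > 0.05
        if mask.sum() < 2:
            continue
        x, y = b.dt[mask], b.c[mask]
        beta_i = float(x @ y) / float(x @ x)
        rates.append(beta_i)
        r = y - beta_i * x
        if r.size > 1:
            resid_vars.append(float(r @ r) / (r.size - 1))
    rv = max(float(np.mean(resid_vars)) if resid_vars else 1.0, 1e-4)
    sb = max(0.5 * float(np.var(rates)) if len(rates) > 1 else 1.0, 1e-4)
    return np.array([sb, 0.25 * rv, 0.15 * rv, 0.2 * rv])


def _setup(blocks):
    if len(blocks) < 2:
        raise RemlError("need at least two subjects")
    patterns = _group_pair_patterns(blocks)
    N = int(sum(p.n * p.m for p in patterns))
    xtx = float(sum(p.m * (p.dt @ p.dt) for p in patterns))
    if xtx <= 0:
        raise RemlError("rank-deficient design: no pairs spanning time")
    if N <= 1:
        raise RemlError("too few pair measurements")
    return patterns, N, np.log(xtx)


def _make_assemble(patterns, N, log_xtx):
    """Criterion/gradient evaluator for one prepared group of subjects."""

    def assemble(theta, want_grad=False):
        s2b, s2u, s2v, s2w = theta
        logdet = 0.0
        S = 0.0
        num = 0.0
        ypy_parts = 0.0
        cache = []
        for pat in patterns:
            sigma = s2b * pat.DD + s2u * pat.MU + s2v * pat.MV + s2w * pat.I
            W, ld = inv_from_cholesky(sigma)
            if W is None:
                return None
            wx = W @ pat.dt
            WC = W @ pat.C
            logdet += pat.m * ld
            S += pat.m * float(pat.dt @ wx)
            num += float(np.sum(wx @ pat.C))
            ypy_parts += float(np.einsum("nm,nm->", pat.C, WC))
            cache.append((W, wx, WC))
        if S <= 0:
            return None
        beta = num / S
        ypy = ypy_parts - num * num / S
        neg2 = (N - 1) * LOG_2PI + logdet + np.log(S) - log_xtx + ypy
        if not want_grad:
            return neg2, beta, 1.0 / S
        # tr(W G_k) - (wx' G_k wx)/S - (Wr)' G_k (Wr), r = c - beta*dt
        tr_term = np.zeros(4)
        h_tot = np.zeros(4)
        r_term = np.zeros(4)
        info = np.zeros((4, 4))
        for pat, (W, wx, WC) in zip(patterns, cache):
            WMU = W @ pat.MU
            WMV = W @ pat.MV
            MUwx = pat.MU @ wx
            MVwx = pat.MV @ wx
            dtwx = float(pat.dt @ wx)
            tr_term += pat.m * np.array(
                [
                    dtwx,
                    float(np.trace(WMU)),
                    float(np.trace(WMV)),
                    float(np.trace(W)),
                ]
            )
            sandwiches = np.array(
                [
                    dtwx * dtwx,
                    float(wx @ MUwx),
                    float(wx @ MVwx),
                    float(wx @ wx),
                ]
            )
            h_tot += pat.m * sandwiches
            WR = WC - beta * wx[:, None]
            dtWR = pat.dt @ WR
            r_term += np.array(
                [
                    float(dtWR @ dtWR),
                    float(np.einsum("nm,nm->", WR, pat.MU @ WR)),
                    float(np.einsum("nm,nm->", WR, pat.MV @ WR)),
                    float(np.einsum("nm,nm->", WR, WR)),
                ]
            )
            # expected information tr(W G_k W G_l); the slope component is
            # rank one, so its row reduces to the wx sandwiches
            info[0] += pat.m * sandwiches
            info[1, 1] += pat.m * float(np.sum(WMU * WMU.T))
            info[1, 2] += pat.m * float(np.sum(WMU * WMV.T))
            info[1, 3] += pat.m * float(np.sum(WMU * W))
            info[2, 2] += pat.m * float(np.sum(WMV * WMV.T))
            info[2, 3] += pat.m * float(np.sum(WMV * W))
            info[3, 3] += pat.m * float(np.sum(W * W))
        for i in range(1, 4):
            for j in range(i):
                info[i, j] = info[j, i]
        grad = tr_term - h_tot / S - r_term
        return neg2, beta, 1.0 / S, grad, info

    return assemble


def restricted_loglik(records, theta) -> float:
    """Restricted log-likelihood at fixed variance components.

    ``records`` is a tidy forward-changes table (or prepared blocks);
    ``theta`` is (sigma2_b, sigma2_u, sigma2_v, sigma2_w).  Returns
    -inf for a singular covariance.
    """
    blocks = (
        prepare_direct_blocks(records)
        if isinstance(records, pd.DataFrame)
        else records
    )
    assemble = _make_assemble(*_setup(blocks))
    out = assemble(np.asarray(theta, dtype=float))
    return -np.inf if out is None else -0.5 * out[0]


def fit_direct_blocks(
    blocks,
    constrain_between: bool = False,
    start=None,
    multi_start: bool = True,
    fix: tuple = (),
) -> DirectModelFit:
    """REML fit of the direct-change model on prepared subject blocks.

    ``fix`` names components ('b', 'u', 'v', 'w') pinned at zero;
    ``constrain_between`` is shorthand for fixing 'b' and 'u'.
    """
    n_subjects = len(blocks)
    patterns, N, log_xtx = _setup(blocks)
    assemble = _make_assemble(patterns, N, log_xtx)

    def neg2_and_grad(theta):
        out = assemble(theta, want_grad=True)
        if out is None:
            return np.inf, None, None
        return out[0], out[3], out[4]

    if start is None:
        start = _direct_moment_start(blocks)
    start = np.asarray(start, dtype=float)
    starts = [start]
    if multi_start:
        starts += [start / 10.0, start * 10.0]

    pinned = set(fix) | ({"b", "u"} if constrain_between else set())
    if not pinned <= {"b", "u", "v", "w"}:
        raise ValueError(f"unknown component in fix: {sorted(pinned)}")
    free = np.array([name not in pinned for name in "buvw"])
    if not free.any():
        raise ValueError("at least one variance component must be free")
    fixed = np.where(free, np.nan, 0.0)
    theta_hat, best, converged, boundary = optimize_reml(
        neg2_and_grad, starts, free, fixed
    )

    out = assemble(np.maximum(theta_hat, 1e-12))
    if out is None:
        return DirectModelFit(
            np.nan, np.nan, *theta_hat, restricted_loglik=np.nan,
            converged=False, boundary=boundary, constrained=constrain_between,
            n_subjects=n_subjects, n_pairs=N,
        )
    _, beta, var_beta = out
    return DirectModelFit(
        beta_hat=float(beta),
        se_beta=float(np.sqrt(var_beta)),
        sigma2_b_hat=float(theta_hat[0]),
        sigma2_u_hat=float(theta_hat[1]),
        sigma2_v_hat=float(theta_hat[2]),
        sigma2_w_hat=float(theta_hat[3]),
        restricted_loglik=-0.5 * best,
        converged=converged,
        boundary=tuple("buvw"[i] for i in boundary),
        constrained=constrain_between,
        n_subjects=n_subjects,
        n_pairs=N,
    )


def fit_direct_model(
    records: pd.DataFrame,
    constrain_between: bool = False,
    start=None,
    multi_start: bool = True,
    fix: tuple = (),
) -> DirectModelFit:
    """Fit the direct-change model to one group/structure's forward records.

    ``constrain_between`` pins sigma2_b = sigma2_u = 0, the fallback
    model used when the full model fails to converge on resamples.
    """
    blocks = prepare_direct_blocks(records)
    return fit_direct_blocks(
        blocks, constrain_between=constrain_between, start=start,
        multi_start=multi_start, fix=fix,
    )


def _components(fit):
    if hasattr(fit, "sigma2_b_hat"):
        return (
            fit.sigma2_b_hat, fit.sigma2_u_hat, fit.sigma2_v_hat, fit.sigma2_w_hat
        )
    return fit.sigma2_b, fit.sigma2_u, fit.sigma2_v, fit.sigma2_w


def predict_change_variance_direct(fit, dt: float, same_day: bool = False) -> float:
    """Variance of a single direct change measure over ``dt`` years."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    s2b, s2u, s2v, s2w = _components(fit)
    visit_term = 0.0 if same_day else 2.0 * s2u
    return dt * dt * s2b + visit_term + 2.0 * s2v + s2w


def predict_rate_variance_direct(fit, dt: float) -> float:
    """Variance of a rate derived from one direct measure over ``dt`` years."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    s2b, s2u, s2v, s2w = _components(fit)
    return s2b + (2.0 * s2u + 2.0 * s2v + s2w) / (dt * dt)
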