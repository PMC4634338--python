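"""Shared restricted-maximum-likelihood machinery.

Both analysis models (repeated volumes, repeated direct changes) are
linear mixed models with block-diagonal covariance over subjects and a
small number of variance components.  Fixed effects are profiled out by
generalized least squares, and the restricted likelihood is maximized
over log-variances.  The REML criterion used throughout is Harville's:

    -2 l_R = (N - p) log(2*pi) + log|Sigma| + log|X' Sigma^-1 X|
             - log|X' X| + y' P y

with P = Sigma^-1 - Sigma^-1 X (X' Sigma^-1 X)^-1 X' Sigma^-1.  The
``- log|X'X|`` term makes the criterion identical to the log-density of
any orthonormal set of error contrasts, which the test suite exploits
as an independent oracle.  The models supply analytic gradients via the
standard identities

    d log|Sigma| / dtheta_k          =  tr(Sigma^-1 G_k)
    d log|X'Sigma^-1 X| / dtheta_k   = -tr(M^-1 X'Sigma^-1 G_k Sigma^-1 X)
    d (y'Py) / dtheta_k              = -(Py)' G_k (Py)

where G_k = dSigma/dtheta_k and Py = Sigma^-1 (y - X beta_gls).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

#: Bounds for log-variance parameters during optimization.
LOG_LB = -30.0
LOG_UB = 8.0

#: Variance estimates below this are truncated to exactly zero (boundary).
TRUNCATION = 1e-8

#: Convergence tolerance on the REML criterion.
CRITERION_TOL = 1e-8

LOG_2PI = float(np.log(2.0 * np.pi))

_BIG = 1e12


class RemlError(RuntimeError):
    """Raised for degenerate model inputs (not for non-convergence)."""


def optimize_reml(neg2_grad_info, starts, free, fixed_values):
    """Minimize a -2*REML criterion over log-variances.

    With several starts, each is run through gradient-based L-BFGS-B
    (with a derivative-free polish when its line search aborts).  A
    single start — the warm-started path used thousands of times inside
    the bootstrap — first tries safeguarded Fisher scoring (Newton steps
    on the expected information with backtracking), which typically
    converges in a handful of criterion evaluations, and falls back to
    L-BFGS-B if it stalls.

    Parameters
    ----------
    neg2_grad_info : callable
        Maps a full variance vector (natural scale) to ``(criterion,
        gradient, expected_information)``; gradient and information are
        on the natural scale and may be None when the criterion is
        infinite.
    starts : sequence of array-like
        Full-length variance vectors to start from.
    free : boolean array
        Which components are optimized; the rest are pinned.
    fixed_values : array-like
        Values of pinned components.

    Returns
    -------
    theta_hat : ndarray
        Estimated variances (natural scale, truncated at zero).
    best : float
        Criterion value at the (untruncated) optimum.
    converged : bool
    boundary : tuple of int
        Indices of components truncated to zero.
    """
    free = np.asarray(free, dtype=bool)
    fixed_values = np.asarray(fixed_values, dtype=float)

    def expand(log_free):
        theta = fixed_values.copy()
        theta[free] = np.exp(log_free)
        return theta

    def objective(log_free):
        theta = expand(log_free)
        val, grad, _ = neg2_grad_info(theta)
        if not np.isfinite(val):
            return _BIG, np.zeros_like(log_free)
        # chain rule for the log parametrization
        return val, grad[free] * theta[free]

    def objective_plain(log_free):
        val, _, _ = neg2_grad_info(expand(log_free))
        return val if np.isfinite(val) else _BIG

    if len(starts) == 1:
        out = _fisher_newton(neg2_grad_info, expand, free, starts[0])
        if out is not None:
            return out

    best = np.inf
    best_x = None
    best_success = False
    for s in starts:
        s = np.asarray(s, dtype=float)[free]
        x0 = np.log(np.clip(s, np.exp(LOG_LB), np.exp(LOG_UB)))
        res = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(LOG_LB, LOG_UB)] * x0.size,
            options={"ftol": CRITERION_TOL * 1e-3, "gtol": 1e-6, "maxiter": 500},
        )
        def small_projected_gradient(x):
            # line searches can abort right at the optimum; a small
            # projected gradient there still means convergence (the
            # curvature in log-variance units is O(10^2), so a gradient
            # of 1e-2 locates the optimum to ~1e-4 log units)
            _, g = objective(x)
            at_lb = x <= LOG_LB + 1e-9
            at_ub = x >= LOG_UB - 1e-9
            pg = np.where(at_lb, np.minimum(g, 0.0), g)
            pg = np.where(at_ub, np.maximum(pg, 0.0), pg)
            return bool(np.max(np.abs(pg)) < 1e-2)

        success = bool(res.success) or small_projected_gradient(res.x)
        if not success:
            # otherwise a derivative-free polish settles it
            res2 = optimize.minimize(
                objective_plain,
                res.x,
                method="Nelder-Mead",
                options={"fatol": CRITERION_TOL, "xatol": 1e-5, "maxiter": 400},
            )
            if res2.fun <= res.fun:
                res = res2
            success = bool(res2.success) or small_projected_gradient(res.x)
        x_clip = np.clip(res.x, LOG_LB, LOG_UB)
        # the lower box bound means a component sits at zero: a legitimate
        # boundary optimum, not a failure
        success = success or bool(np.any(x_clip <= LOG_LB + 1e-6))
        # starts landing within 1e-6 of the incumbent found the same
        # optimum up to numerical noise and share convergence status
        if res.fun < best - 1e-6:
            best, best_x, best_success = res.fun, x_clip, success
        elif res.fun < best + 1e-6:
            if res.fun < best:
                best, best_x = res.fun, x_clip
            best_success = best_success or success
    if best_x is None:  # pragma: no cover - all starts failed hard
        theta = fixed_values.copy()
        return theta, np.inf, False, ()

    theta_hat = expand(best_x)
    boundary = tuple(
        int(i) for i in np.nonzero(free & (theta_hat < TRUNCATION))[0]
    )
    theta_hat[list(boundary)] = 0.0
    return theta_hat, float(best), bool(best_success), boundary


def _fisher_newton(neg2_grad_info, expand, free, start, max_iter=40):
    """Safeguarded Fisher-scoring on log-variances from a warm start.

    Returns the standard (theta_hat, best, converged, boundary) tuple,
    or None to signal that the caller should fall back to L-BFGS-B.
    """
    x = np.log(
        np.clip(np.asarray(start, dtype=float)[free], np.exp(LOG_LB), np.exp(LOG_UB))
    )
    f, g_nat, H_nat = neg2_grad_info(expand(x))
    if not np.isfinite(f):
        return None
    converged = False
    for _ in range(max_iter):
        theta_f = expand(x)[free]
        g = g_nat[free] * theta_f
        H = (
            theta_f[:, None] * H_nat[np.ix_(free, free)] * theta_f[None, :]
            + np.diag(g)
        )
        at_lb = x <= LOG_LB + 1e-9
        pg = np.where(at_lb, np.minimum(g, 0.0), g)
        if np.max(np.abs(pg)) < 1e-5:
            converged = True
            break
        step = None
        ridge = 0.0
        for _try in range(6):
            try:
                Hr = H + ridge * np.eye(H.shape[0])
                np.linalg.cholesky(Hr)  # SPD check
                step = np.linalg.solve(Hr, -g)
                break
            except np.linalg.LinAlgError:
                ridge = max(2.0 * ridge, 1e-4 * max(np.abs(np.diag(H)).max(), 1.0))
        if step is None:
            return None
        norm = np.max(np.abs(step))
        if norm > 4.0:
            step *= 4.0 / norm
        accepted = False
        t = 1.0
        for _halve in range(12):
            x_new = np.clip(x + t * step, LOG_LB, LOG_UB)
            f_new, g_new, H_new = neg2_grad_info(expand(x_new))
            if np.isfinite(f_new) and f_new <= f:
                improved = f - f_new
                x, f, g_nat, H_nat = x_new, f_new, g_new, H_new
                accepted = True
                if improved < CRITERION_TOL:
                    converged = True
                break
            t *= 0.5
        if not accepted:
            # cannot decrease further: converged if the gradient is modest
            converged = np.max(np.abs(pg)) < 1e-2
            break
        if converged:
            # check the first-order condition once more at the new point
            theta_f = expand(x)[free]
            g = g_nat[free] * theta_f
            at_lb = x <= LOG_LB + 1e-9
            pg = np.where(at_lb, np.minimum(g, 0.0), g)
            converged = np.max(np.abs(pg)) < 1e-2
            break
    if not converged:
        return None
    theta_hat = expand(x)
    boundary = tuple(
        int(i) for i in np.nonzero(free & (theta_hat < TRUNCATION))[0]
    )
    theta_hat[list(boundary)] = 0.0
    return theta_hat, float(f), True, boundary


def inv_from_cholesky(sigma):
    """(inverse, logdet) of a covariance block, or (None, None) if not PD."""
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return None, None
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    Linv = np.linalg.inv(L)
    return Linv.T @ Linv, logdet
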