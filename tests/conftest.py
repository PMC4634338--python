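"""Shared fixtures and independent brute-force oracles.

The REML oracle here deliberately avoids every shortcut the package
takes: it materializes the full observation covariance matrix, builds
the fixed-effects design explicitly, forms an orthonormal basis of
error contrasts with :func:`scipy.linalg.null_space`, and evaluates the
multivariate-normal log-density of the contrasted data directly.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _hsettings
from scipy.linalg import null_space
from scipy.stats import multivariate_normal

_hsettings.register_profile("repeatable", derandomize=True)
_hsettings.load_profile("repeatable")

from atrophystats import StudyDesign
from atrophystats.synthetic import (
    default_presets,
    make_subjects,
    simulate_direct_dataset,
    simulate_volume_dataset,
)


@pytest.fixture(scope="session")
def full_design():
    return StudyDesign()


@pytest.fixture(scope="session")
def small_design():
    """Trimmed schedule for fast model fits (still identifies all components)."""
    return StudyDesign(visit_weeks=(0, 2, 26, 52), n_cases=8, n_controls=4)


@pytest.fixture(scope="session")
def brain_params():
    vol = {g: default_presets("brain", g)[0] for g in ("AD", "control")}
    direct = {g: default_presets("brain", g)[1] for g in ("AD", "control")}
    return vol, direct


@pytest.fixture(scope="session")
def brain_volumes(full_design, brain_params):
    return simulate_volume_dataset(full_design, brain_params[0], seed=101)


@pytest.fixture(scope="session")
def brain_changes(full_design, brain_params):
    return simulate_direct_dataset(full_design, brain_params[1], seed=202)


def full_attendance(design):
    return {
        s: tuple(range(1, design.n_visits + 1)) for s, _ in make_subjects(design)
    }


# ---------------------------------------------------------------------------
# Brute-force REML oracles
# ---------------------------------------------------------------------------


def _contrast_loglik(y, X, sigma):
    K = null_space(X.T)
    z = K.T @ y
    return float(
        multivariate_normal.logpdf(z, mean=np.zeros(z.size), cov=K.T @ sigma @ K)
    )


def volume_reml_oracle(records: pd.DataFrame, theta) -> float:
    """Restricted log-likelihood via dense matrices and error contrasts."""
    s2b, s2d, s2e = theta
    df = records.sort_values(["subject", "visit", "scan"]).reset_index(drop=True)
    subjects = list(dict.fromkeys(df["subject"]))
    n_total = len(df)
    y = (
        df["y"].to_numpy(dtype=float)
        if "y" in df.columns
        else 100.0 * np.log(df["volume"].to_numpy(dtype=float))
    )
    X = np.zeros((n_total, len(subjects) + 1))
    sigma = np.zeros((n_total, n_total))
    for si, subj in enumerate(subjects):
        ix = np.flatnonzero((df["subject"] == subj).to_numpy())
        t = df.loc[ix, "time_years"].to_numpy(dtype=float)
        v = df.loc[ix, "visit"].to_numpy()
        X[ix, si] = 1.0
        X[ix, -1] = t
        block = (
            s2b * np.outer(t, t)
            + s2d * (v[:, None] == v[None, :]).astype(float)
            + s2e * np.eye(len(ix))
        )
        sigma[np.ix_(ix, ix)] = block
    return _contrast_loglik(y, X, sigma)


def direct_reml_oracle(records: pd.DataFrame, theta) -> float:
    """Restricted log-likelihood of forward direct changes, dense route."""
    s2b, s2u, s2v, s2w = theta
    df = records[records["direction"] == "forward"].sort_values(
        ["subject", "start_visit", "start_scan", "end_visit", "end_scan"]
    ).reset_index(drop=True)
    subjects = list(dict.fromkeys(df["subject"]))
    n_total = len(df)
    y = df["change"].to_numpy(dtype=float)
    X = df["delta_t_years"].to_numpy(dtype=float).reshape(-1, 1)
    sigma = np.zeros((n_total, n_total))
    for subj in subjects:
        ix = np.flatnonzero((df["subject"] == subj).to_numpy())
        g = df.loc[ix]
        dt = g["delta_t_years"].to_numpy(dtype=float)
        starts = list(zip(g["start_visit"], g["start_scan"]))
        ends = list(zip(g["end_visit"], g["end_scan"]))
        n = len(ix)
        block = s2b * np.outer(dt, dt) + s2w * np.eye(n)
        for p in range(n):
            for q in range(n):
                sv = 0.0
                for visit, sign in ((starts[p][0], -1), (ends[p][0], 1)):
                    for visit2, sign2 in ((starts[q][0], -1), (ends[q][0], 1)):
                        if visit == visit2:
                            sv += sign * sign2
                ss = 0.0
                for scan, sign in ((starts[p], -1), (ends[p], 1)):
                    for scan2, sign2 in ((starts[q], -1), (ends[q], 1)):
                        if scan == scan2:
                            ss += sign * sign2
                block[p, q] += s2u * sv + s2v * ss
        sigma[np.ix_(ix, ix)] = block
    return _contrast_loglik(y, X, sigma)
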