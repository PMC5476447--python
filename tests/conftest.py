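"""Shared fixtures: small exact rank-one covariance pairs and sessions."""

from __future__ import annotations

import numpy as np
import pytest

from attncov.session import SessionGroundTruth, construct_covariances


def exact_rank1_pair(n_units: int, seed: int = 0,
                     g: np.ndarray | None = None):
    """Exact (noiseless) unattended/attended covariance pair with known g.

    C_U = diag(private) + x x^T and C_A off-diagonal = (g*x)(g*x)^T, so the
    attended matrix decomposes exactly as g_i g_j C_U(i, j) off-diagonal.
    """
    rng = np.random.default_rng(seed)
    lam = rng.uniform(2.0, 8.0, n_units)
    u = rng.uniform(0.6, 1.4, n_units)
    x = 0.45 * np.sqrt(lam) * u
    private = lam - x ** 2
    if g is None:
        g = rng.uniform(0.5, 1.1, n_units)
    truth = SessionGroundTruth(g_true=g, rates_U=lam / 0.2,
                               rates_A=lam / 0.2, x_loading=x,
                               private_var=private)
    C_U, C_A = construct_covariances(truth)
    return C_U, C_A, truth


def generic_rank1_pair(n_units: int, seed: int = 0):
    """Exact rank-one pair with generic (mixed-sign) loadings.

    Emulates a random covariance matrix whose single shared dimension has
    loadings of either sign, the regime in which residual structure found
    by the fit in shuffled matrices is a pure finite-size effect.
    """
    rng = np.random.default_rng(seed)
    lam = rng.uniform(2.0, 8.0, n_units)
    x = 0.45 * np.sqrt(lam) * rng.uniform(0.6, 1.4, n_units) \
        * rng.choice([-1.0, 1.0], n_units)
    g = rng.uniform(0.5, 1.1, n_units)
    C_U = np.outer(x, x) + np.diag(lam - x ** 2)
    gx = g * x
    C_A = np.outer(gx, gx)
    np.fill_diagonal(C_A, lam)
    return C_U, C_A, g


@pytest.fixture(scope="session")
def small_session():
    """One modest synthetic session reused by several tests."""
    from attncov.session import make_session
    return make_session(16, 250, seed=11)


@pytest.fixture(scope="session")
def small_session_covs(small_session):
    from attncov.covstats import count_covariance
    return (count_covariance(small_session.unattended),
            count_covariance(small_session.attended))
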