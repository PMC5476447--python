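"""Rank-one model of attentional covariance modulation.

The model states that the attended spike-count covariance equals the
unattended one with every off-diagonal entry scaled by a product of
per-unit covariance gains:

    C_A(i, j) = g_i * g_j * C_U(i, j),   i != j.

For N > 3 units this is an overdetermined system of N(N-1)/2 equations in N
unknowns; the gains are estimated by least-squares minimization of

    f(g) = sum_{i<j} ( g_i C_U(i,j) g_j - C_A(i,j) )^2.

Fit quality rho is the Pearson correlation between measured and predicted
attended covariances over the strictly-upper off-diagonal entries
(variances are excluded so the statistic measures covariance modulation
only).  Two null models bracket rho: a shuffle null (structure destroyed,
rho_shuf -> 0 for large N) and a finite-trial upper bound (perfectly
decomposable covariance resampled with the experimental trial count,
rho_ub -> 1 as trials -> infinity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import pearsonr

from .covstats import CovarianceEstimate
from .session import sample_correlated_poisson

__all__ = [
    "Rank1Solution",
    "NullEnsemble",
    "LoocvResult",
    "fit_rank1",
    "shuffled_null",
    "upper_bound",
    "loocv",
    "normalized_performance",
    "split_population_g",
    "g_vs_rate_modulation",
]


@dataclass
class Rank1Solution:
    g: np.ndarray
    predicted_CA: np.ndarray
    rho: float
    residual: float
    n_restarts_used: int


@dataclass
class NullEnsemble:
    rho_shuf: np.ndarray
    rho_ub: np.ndarray
    n_shuffles: int
    n_realizations: int
    n_trials_ub: int
    seed: int


@dataclass
class LoocvResult:
    held_out_actual: np.ndarray
    held_out_predicted: np.ndarray
    rho_cv: float
    n_systems: int


def _as_matrix(C) -> np.ndarray:
    if isinstance(C, CovarianceEstimate):
        return C.matrix
    return np.asarray(C, dtype=float)


def _objective_terms(cu: np.ndarray, ca: np.ndarray,
                     ii: np.ndarray, jj: np.ndarray, n: int):
    """Objective and analytic gradient over the retained (i<j) equations."""

    def f(g: np.ndarray) -> float:
        e = g[ii] * cu * g[jj] - ca
        return float(e @ e)

    def grad(g: np.ndarray) -> np.ndarray:
        e = g[ii] * cu * g[jj] - ca
        out = np.zeros(n)
        np.add.at(out, ii, 2.0 * e * cu * g[jj])
        np.add.at(out, jj, 2.0 * e * cu * g[ii])
        return out

    return f, grad


def fit_rank1(C_U, C_A, n_restarts: int = 3, seed: int = 0,
              mask_pair: tuple[int, int] | None = None,
              g0: np.ndarray | None = None) -> Rank1Solution:
    """Least-squares fit of the per-unit covariance gains.

    Quasi-Newton (BFGS) minimization from an all-ones start plus
    ``n_restarts`` multiplicatively perturbed restarts (lognormal,
    sigma=0.2); the lowest-residual solution wins.  The objective is
    invariant under g -> -g, so the solution is reported with nonnegative
    mean.  ``mask_pair`` drops one equation (used by cross-validation);
    ``g0`` overrides the central initialization (warm starts).
    """
    CU, CA = _as_matrix(C_U), _as_matrix(C_A)
    n = CU.shape[0]
    if n < 4:
        raise ValueError("rank-one fit is underdetermined for N < 4")
    if CU.shape != CA.shape:
        raise ValueError("covariance matrices must have matching unit sets")
    ii, jj = np.triu_indices(n, k=1)
    keep = np.ones(ii.size, dtype=bool)
    if mask_pair is not None:
        a, b = min(mask_pair), max(mask_pair)
        keep &= ~((ii == a) & (jj == b))
    cu, ca = CU[ii, jj][keep], CA[ii, jj][keep]
    if np.all(cu == 0):
        raise ValueError("degenerate system: all off-diagonal C_U entries zero")
    f, grad = _objective_terms(cu, ca, ii[keep], jj[keep], n)

    rng = np.random.default_rng(seed)
    start = np.ones(n) if g0 is None else np.asarray(g0, dtype=float)
    starts = [start]
    for _ in range(max(n_restarts, 0)):
        starts.append(start * rng.lognormal(0.0, 0.2, size=n))
    best = None
    for x0 in starts:
        res = optimize.minimize(f, x0, jac=grad, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    g = best.x
    if g.mean() < 0:
        g = -g
    predicted = np.outer(g, g) * CU
    np.fill_diagonal(predicted, np.diag(CA))
    pred_off = predicted[ii, jj]
    meas_off = CA[ii, jj]
    if np.std(pred_off) == 0 or np.std(meas_off) == 0:
        rho = np.nan
    else:
        rho = float(pearsonr(meas_off, pred_off)[0])
    return Rank1Solution(g=g, predicted_CA=predicted, rho=rho,
                         residual=float(best.fun),
                         n_restarts_used=len(starts) - 1)


# ---------------------------------------------------------------------------
# Null models
# ---------------------------------------------------------------------------

def _principal_sqrt(C: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    if w.min() < -tol:
        raise ValueError(f"matrix is not PSD (min eigenvalue {w.min():.2e})")
    return (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T


def shuffle_covariance(C_A: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """PSD-preserving shuffle: permute the strictly-upper entries of the
    principal square root (diagonal fixed, lower triangle mirrored) and
    square the result."""
    R = _principal_sqrt(C_A)
    n = R.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = R[iu]
    perm = rng.permutation(vals.size)
    D = np.diag(np.diag(R)).astype(float)
    D[iu] = vals[perm]
    D = D + np.triu(D, k=1).T
    return np.real(D @ D)


def shuffled_null(C_U, C_A, n_shuffles: int = 100, seed: int = 0,
                  n_restarts: int = 1) -> np.ndarray:
    """Fit correlations against shuffled attended covariances."""
    CU, CA = _as_matrix(C_U), _as_matrix(C_A)
    rng = np.random.default_rng(seed)
    rhos = np.empty(n_shuffles)
    for k in range(n_shuffles):
        C_shuf = shuffle_covariance(CA, rng)
        sol = fit_rank1(CU, C_shuf, n_restarts=n_restarts,
                        seed=int(rng.integers(2 ** 31)))
        rhos[k] = sol.rho
    return rhos


def upper_bound(C_U, C_A, rates_A: np.ndarray, n_trials: int | None,
                n_realizations: int = 10, seed: int = 0,
                n_restarts: int = 1,
                solution: Rank1Solution | None = None) -> np.ndarray:
    """Finite-trial upper bound on the rank-one fit correlation.

    The fitted prediction ``C_hat_A`` decomposes perfectly by construction;
    resampling it as correlated Poisson counts with the experimental trial
    count quantifies how much estimation noise alone degrades rho.
    ``n_trials=None`` skips sampling (the infinite-trial limit, rho_ub = 1).
    ``rates_A`` are attended mean counts per window (Poisson marginals).
    """
    CU, CA = _as_matrix(C_U), _as_matrix(C_A)
    rates_A = np.asarray(rates_A, dtype=float)
    if np.any(rates_A <= 0):
        raise ValueError("attended rates must be positive")
    if solution is None:
        solution = fit_rank1(CU, CA, n_restarts=n_restarts, seed=seed)
    target = solution.predicted_CA.copy()
    np.fill_diagonal(target, rates_A)  # Poisson count variance = mean
    rng = np.random.default_rng(seed)
    ii, jj = np.triu_indices(CU.shape[0], k=1)
    if n_trials is None or np.isinf(n_trials):
        sol = fit_rank1(CU, target, n_restarts=n_restarts,
                        seed=int(rng.integers(2 ** 31)))
        return np.array([sol.rho])
    rhos = np.empty(n_realizations)
    for k in range(n_realizations):
        scm = sample_correlated_poisson(rates_A, target, int(n_trials), rng)
        C_ub = np.cov(scm.counts.astype(float), ddof=1)
        sol = fit_rank1(CU, C_ub, n_restarts=n_restarts,
                        seed=int(rng.integers(2 ** 31)))
        rhos[k] = sol.rho
    return rhos


# ---------------------------------------------------------------------------
# Cross-validation and intrinsic-gain checks
# ---------------------------------------------------------------------------

def loocv(C_U, C_A, max_systems: int = 1000, seed: int = 0,
          n_restarts: int = 0) -> LoocvResult:
    """Leave-one-equation-out cross-validation of the rank-one model.

    Each selected pair (a, b) is removed from the system, the gains refit
    (warm-started from the full-system solution), and the held-out
    covariance predicted as ``g_ab(a) g_ab(b) C_U(a, b)``.  When the pair
    count exceeds ``max_systems`` (capped at min(max_systems, N(N-1)/2)),
    systems are chosen uniformly without replacement.
    """
    CU, CA = _as_matrix(C_U), _as_matrix(C_A)
    n = CU.shape[0]
    if n < 5:
        raise ValueError("leave-one-out needs N >= 5 to stay overdetermined")
    rng = np.random.default_rng(seed)
    full = fit_rank1(CU, CA, n_restarts=max(n_restarts, 1), seed=seed)
    ii, jj = np.triu_indices(n, k=1)
    n_pairs = ii.size
    n_sys = min(max_systems, n_pairs)
    idx = rng.choice(n_pairs, size=n_sys, replace=False) \
        if n_sys < n_pairs else np.arange(n_pairs)
    actual = np.empty(n_sys)
    predicted = np.empty(n_sys)
    for k, p in enumerate(idx):
        a, b = int(ii[p]), int(jj[p])
        sol = fit_rank1(CU, CA, n_restarts=n_restarts,
                        seed=int(rng.integers(2 ** 31)),
                        mask_pair=(a, b), g0=full.g)
        actual[k] = CA[a, b]
        predicted[k] = sol.g[a] * sol.g[b] * CU[a, b]
    rho_cv = float(pearsonr(actual, predicted)[0])
    return LoocvResult(held_out_actual=actual, held_out_predicted=predicted,
                       rho_cv=rho_cv, n_systems=n_sys)


def normalized_performance(rho: float, rho_shuf_mean: float,
                           rho_ub_mean: float) -> tuple[float, float]:
    """Session performance normalized by the finite-trial upper bound."""
    if rho_ub_mean == 0:
        raise ZeroDivisionError("rho_ub mean is zero; cannot normalize")
    return rho / rho_ub_mean, rho_shuf_mean / rho_ub_mean


def split_population_g(C_U, C_A, set_1, set_2, shared: int,
                       n_restarts: int = 1, seed: int = 0) -> tuple[float, float]:
    """Estimate one unit's gain from two populations overlapping only in it.

    If the covariance gain is intrinsic to the neuron, the two estimates
    should agree.
    """
    set_1, set_2 = list(set_1), list(set_2)
    overlap = set(set_1) & set(set_2)
    if overlap != {shared}:
        raise ValueError("sets must overlap in exactly the shared unit")
    if len(set_1) < 4 or len(set_2) < 4:
        raise ValueError("each set needs at least 4 units")
    CU, CA = _as_matrix(C_U), _as_matrix(C_A)
    out = []
    for k, units in enumerate((set_1, set_2)):
        sub = np.ix_(units, units)
        sol = fit_rank1(CU[sub], CA[sub], n_restarts=n_restarts,
                        seed=seed + k)
        out.append(float(sol.g[units.index(shared)]))
    return out[0], out[1]


def g_vs_rate_modulation(g: np.ndarray, rates_U: np.ndarray,
                         rates_A: np.ndarray) -> float:
    """Pearson correlation between covariance gains and rate modulation.

    Rate modulation is the per-unit attended/unattended rate ratio.  Units
    with zero unattended rate are flagged (dropped with a warning via NaN
    masking).
    """
    g = np.asarray(g, dtype=float)
    rates_U = np.asarray(rates_U, dtype=float)
    rates_A = np.asarray(rates_A, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rates_U > 0, rates_A / rates_U, np.nan)
    ok = np.isfinite(ratio)
    if ok.sum() < 2:
        raise ValueError("fewer than two units with positive unattended rate")
    return float(pearsonr(g[ok], ratio[ok])[0])
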