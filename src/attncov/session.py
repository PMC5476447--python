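"""Synthetic attended/unattended spike-count sessions.

The recordings this package analyzes are trial-by-trial spike counts from a
population of visual-cortex units under two attention conditions.  This
module generates surrogate sessions with a *known* covariance structure:

* the unattended count covariance is rank-one-plus-diagonal,
  ``C_U = diag(private_var) + x x^T``, mimicking populations whose shared
  variability is dominated by a single global fluctuation;
* the attended off-diagonal covariance is the unattended one scaled
  elementwise by ``g_i g_j`` with per-unit covariance gains ``g_i``
  (mostly below one, so attention reduces shared variability).

Counts are sampled from a latent-Gaussian (Gaussian copula) model with
Poisson marginals; the same sampler provides the finite-trial surrogate used
by the rank-one fit's upper-bound null.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.special import ndtr, ndtri
from scipy.stats import poisson

__all__ = [
    "SpikeCountMatrix",
    "SessionGroundTruth",
    "SessionData",
    "DegenerateCovarianceError",
    "latent_corr_for_target",
    "sample_correlated_poisson",
    "make_session",
    "write_session",
    "read_session",
]


class DegenerateCovarianceError(ValueError):
    """Raised when a target covariance cannot be realized by the copula."""


@dataclass
class SpikeCountMatrix:
    """Integer spike counts, one row per unit, one column per trial."""

    counts: np.ndarray
    unit_ids: list[str]
    condition: str
    window_s: float = 0.2

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (units x trials) array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(self.unit_ids) != self.counts.shape[0]:
            raise ValueError("unit_ids length must equal the number of rows")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    def mean_counts(self) -> np.ndarray:
        return self.counts.mean(axis=1)

    def mean_rates(self) -> np.ndarray:
        """Mean firing rates in spikes/s."""
        return self.mean_counts() / self.window_s


@dataclass
class SessionGroundTruth:
    """Generative parameters of a synthetic session."""

    g_true: np.ndarray
    rates_U: np.ndarray
    rates_A: np.ndarray
    x_loading: np.ndarray
    private_var: np.ndarray

    def __post_init__(self) -> None:
        vecs = [self.g_true, self.rates_U, self.rates_A, self.x_loading,
                self.private_var]
        vecs = [np.asarray(v, dtype=float) for v in vecs]
        (self.g_true, self.rates_U, self.rates_A, self.x_loading,
         self.private_var) = vecs
        n = self.g_true.size
        if any(v.size != n for v in vecs):
            raise ValueError("all ground-truth vectors must share a length")
        if np.any(self.rates_U < 0) or np.any(self.rates_A < 0):
            raise ValueError("rates must be nonnegative")
        if np.any(self.private_var < 0):
            raise ValueError("private_var must be nonnegative")


@dataclass
class SessionData:
    unattended: SpikeCountMatrix
    attended: SpikeCountMatrix
    truth: SessionGroundTruth | None = None

    def __post_init__(self) -> None:
        if self.unattended.unit_ids != self.attended.unit_ids:
            raise ValueError("conditions must share unit_ids in order")


# ---------------------------------------------------------------------------
# Latent-Gaussian (copula) machinery
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = leggauss(96)
_Z_HI = 8.5  # standard-normal mass beyond this is < 1e-17


class _PoissonPair:
    """Precomputed quantities for the count correlation of one pair.

    For Poisson marginals with means ``lam_i, lam_j`` coupled through a
    bivariate-normal copula with latent correlation ``rho``, the count
    covariance is

        Cov(X, Y) = sum_{k>=1} sum_{l>=1} [ P(X>=k, Y>=l) - P(X>=k)P(Y>=l) ]

    and the upper-quadrant probabilities reduce to one-dimensional normal
    integrals evaluated here by Gauss-Legendre quadrature.
    """

    def __init__(self, lam_i: float, lam_j: float):
        if lam_i <= 0 or lam_j <= 0:
            raise ValueError("Poisson rates must be positive")
        self.lam_i = float(lam_i)
        self.lam_j = float(lam_j)
        self.a, self.pa = self._thresholds(lam_i)   # P(X >= k) = pa
        self.b, self.pb = self._thresholds(lam_j)
        self.sd = np.sqrt(lam_i * lam_j)

    @staticmethod
    def _thresholds(lam: float) -> tuple[np.ndarray, np.ndarray]:
        kmax = int(poisson.isf(1e-13, lam)) + 1
        k = np.arange(1, kmax + 1)
        cdf = poisson.cdf(k - 1, lam)
        # latent threshold for the event {count >= k}
        thr = ndtri(np.clip(cdf, 1e-300, 1 - 1e-16))
        tail = poisson.sf(k - 1, lam)
        keep = thr < _Z_HI
        return thr[keep], tail[keep]

    def corr(self, rho: float) -> float:
        """Pearson correlation of the counts at latent correlation rho."""
        if rho == 0.0:
            return 0.0
        rho = float(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
        s = np.sqrt(1.0 - rho * rho)
        a = self.a[:, None]                                    # (K, 1)
        lo = np.maximum(a, -_Z_HI)
        half = 0.5 * (_Z_HI - lo)                              # (K, 1)
        z = lo + half * (_GL_NODES[None, :] + 1.0)             # (K, n)
        phi = np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi)
        # P(Z2 > b | Z1 = z) for every b, vectorized to (K, n, L)
        arg = (self.b[None, None, :] - rho * z[:, :, None]) / s
        inner = ndtr(-arg)
        integrand = phi[:, :, None] * inner
        quad = np.einsum("n,knl->kl", _GL_WEIGHTS, integrand) * half[:, :1]
        cov = float(np.sum(quad - self.pa[:, None] * self.pb[None, :]))
        return cov / self.sd


def latent_corr_for_target(lambda_i: float, lambda_j: float,
                           target_corr: float, tol: float = 1e-3) -> float:
    """Latent-normal correlation achieving a target Poisson count correlation.

    Inverts the copula map by bisection.  If ``target_corr`` exceeds the
    attainable range for the given marginals the boundary value is returned
    and a warning is issued.
    """
    if lambda_i <= 0 or lambda_j <= 0:
        raise ValueError("Poisson rates must be positive")
    if abs(target_corr) > 1:
        raise ValueError("target correlation must lie in [-1, 1]")
    if target_corr == 0.0:
        return 0.0
    pair = _PoissonPair(lambda_i, lambda_j)
    return _invert_pair(pair, target_corr, tol)


def _invert_pair(pair: _PoissonPair, target: float, tol: float = 1e-3) -> float:
    """Illinois (modified regula falsi) inversion of the monotone copula map.

    The count correlation is close to linear in the latent correlation, so
    this typically converges in a handful of evaluations.
    """
    rho_edge = (1.0 - 1e-9) * np.sign(target)
    bound = pair.corr(rho_edge)
    if (target > 0 and target >= bound) or (target < 0 and target <= bound):
        warnings.warn(
            f"target correlation {target:.4f} is outside the attainable "
            f"range (edge {bound:.4f}) for these Poisson marginals; clipped",
            RuntimeWarning, stacklevel=3)
        return rho_edge
    # bracket endpoints: corr(0) = 0 and corr(edge) = bound
    a, fa = 0.0, -target
    b, fb = rho_edge, bound - target
    for _ in range(60):
        c = (a * fb - b * fa) / (fb - fa)
        fc = pair.corr(c) - target
        if abs(fc) < 0.2 * tol or abs(b - a) < 1e-10:
            return c
        if fa * fc < 0:
            b, fb = c, fc
            fa *= 0.5
        else:
            a, fa = c, fc
    return c


def _latent_matrix(rates: np.ndarray, target_cov: np.ndarray,
                   tol: float = 1e-3) -> tuple[np.ndarray, float, tuple[int, int]]:
    """Pairwise latent correlation matrix and the worst PSD-repair shift."""
    n = rates.size
    target_corr = np.zeros((n, n))
    latent = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            tc = target_cov[i, j] / np.sqrt(rates[i] * rates[j])
            tc = float(np.clip(tc, -1.0, 1.0))
            target_corr[i, j] = target_corr[j, i] = tc
            if tc != 0.0:
                pair = _PoissonPair(rates[i], rates[j])
                r = _invert_pair(pair, tc, tol)
                latent[i, j] = latent[j, i] = r
    repaired, shift, worst = _nearest_psd_corr(latent)
    return repaired, shift, worst


def _nearest_psd_corr(R: np.ndarray) -> tuple[np.ndarray, float, tuple[int, int]]:
    """Eigenvalue-clipped PSD repair with the diagonal renormalized to 1."""
    w, V = np.linalg.eigh(R)
    if w.min() >= -1e-12:
        return R, 0.0, (0, 0)
    w = np.clip(w, 0.0, None)
    M = (V * w) @ V.T
    d = np.sqrt(np.clip(np.diag(M), 1e-12, None))
    M = M / np.outer(d, d)
    np.fill_diagonal(M, 1.0)
    delta = np.abs(M - R)
    np.fill_diagonal(delta, 0.0)
    worst_flat = int(np.argmax(delta))
    worst = np.unravel_index(worst_flat, delta.shape)
    return M, float(delta[worst]), (int(worst[0]), int(worst[1]))


def sample_correlated_poisson(rates: np.ndarray, target_cov: np.ndarray,
                              n_trials: int, seed: int | np.random.Generator,
                              unit_ids: list[str] | None = None,
                              condition: str = "unattended",
                              window_s: float = 0.2,
                              max_repair_shift: float = 0.1) -> SpikeCountMatrix:
    """Sample correlated Poisson counts from a latent multivariate Gaussian.

    ``rates`` are mean counts per window.  Off-diagonal entries of
    ``target_cov`` set the pairwise count covariances (the diagonal is
    implied by the Poisson marginals).  The latent correlation matrix from
    pairwise inversion is repaired to the nearest positive-semidefinite
    correlation matrix; a repair that moves any latent correlation by more
    than ``max_repair_shift`` raises :class:`DegenerateCovarianceError`.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    if n_trials < 2:
        raise ValueError("n_trials must be at least 2")
    target_cov = np.asarray(target_cov, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    latent, shift, worst = _latent_matrix(rates, target_cov)
    if shift > max_repair_shift:
        raise DegenerateCovarianceError(
            f"PSD repair moved the latent correlation of pair {worst} by "
            f"{shift:.3f} (> {max_repair_shift}); target covariance is not "
            "realizable as a correlated Poisson count covariance")
    # sample latent normals, transform marginals through the Poisson ppf
    w, V = np.linalg.eigh(latent)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    z = root @ rng.standard_normal((rates.size, n_trials))
    u = ndtr(z)
    counts = poisson.ppf(np.clip(u, 1e-300, 1 - 1e-16),
                         rates[:, None]).astype(np.int64)
    if unit_ids is None:
        unit_ids = [f"u{i:03d}" for i in range(rates.size)]
    return SpikeCountMatrix(counts=counts, unit_ids=unit_ids,
                            condition=condition, window_s=window_s)


# ---------------------------------------------------------------------------
# Session construction
# ---------------------------------------------------------------------------

def construct_covariances(truth: SessionGroundTruth,
                          window_s: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Exact count covariance matrices implied by the ground truth.

    ``C_U = diag(private_var) + x x^T`` so that off-diagonal entries are
    ``x_i x_j`` and the attended off-diagonal is exactly
    ``g_i g_j C_U(i, j) = (g_i x_i)(g_j x_j)``.  Diagonals equal the
    Poisson count variances of each condition.
    """
    x = truth.x_loading
    C_U = np.outer(x, x) + np.diag(truth.private_var)
    gx = truth.g_true * x
    C_A = np.outer(gx, gx)
    np.fill_diagonal(C_A, truth.rates_A * window_s)
    return C_U, C_A


def make_session(n_units: int, n_trials: int,
                 rate_range: tuple[float, float] = (10.0, 40.0),
                 g_sampler=None, loading_scale: float = 0.45,
                 rate_mod_range: tuple[float, float] = (0.95, 1.20),
                 presentations_per_trial: int = 3,
                 window_s: float = 0.2, seed: int = 0) -> SessionData:
    """Generate one synthetic attended/unattended session.

    Defaults emulate the array-recording regime the analysis targets:
    200 ms count windows, per-unit rates 10-40 spikes/s (mean counts 2-8),
    a single global latent dimension dominating the shared variability,
    covariance gains drawn uniformly on [0.5, 1.1] (mostly < 1, attention
    reduces shared variability) and an independent modest attentional rate
    increase (~7% on average).  Each behavioral trial contributes
    ``presentations_per_trial`` stimulus presentations collapsed to
    exchangeable count windows, so the covariance sample size is
    ``n_trials * presentations_per_trial`` windows per condition.

    Parameters
    ----------
    g_sampler : callable(rng, n) -> ndarray, optional
        Draws the per-unit covariance gains.  Defaults to
        ``uniform(0.5, 1.1)``.  Nonpositive draws raise ``ValueError``.
    loading_scale : float
        Scale of the rank-one loading relative to the count noise SD; sets
        the typical unattended noise correlation (~loading_scale**2 times
        the squared loading heterogeneity).  The default makes the global
        component strong enough that per-unit covariance gains are
        identifiable at session scale (tens of units, ~10^3 trials); see
        the methods note for the trade-off against datasets with weaker
        mean correlations.
    """
    if n_units < 4:
        raise ValueError("need at least 4 units")
    if n_trials < 2:
        raise ValueError("need at least 2 trials per condition")
    if presentations_per_trial < 1:
        raise ValueError("presentations_per_trial must be >= 1")
    n_windows = n_trials * presentations_per_trial
    rng = np.random.default_rng(seed)
    rates_U = rng.uniform(*rate_range, size=n_units)            # sp/s
    lam_U = rates_U * window_s                                  # mean counts
    if g_sampler is None:
        g = rng.uniform(0.5, 1.1, size=n_units)
    else:
        g = np.asarray(g_sampler(rng, n_units), dtype=float)
    if np.any(g <= 0):
        raise ValueError("g_sampler must produce positive gains")
    # heterogeneous positive rank-one loading, scaled to the count SD;
    # every unit keeps a substantial loading so its covariance gain stays
    # identifiable, while the spread produces a broad covariance range
    u = rng.uniform(0.6, 1.4, size=n_units)
    x = loading_scale * np.sqrt(lam_U) * u
    private_var = lam_U - x ** 2
    if np.any(private_var <= 0):  # pragma: no cover - needs loading_scale ~ 1
        raise ValueError("loading_scale too large: private variance <= 0")
    rate_mod = rng.uniform(*rate_mod_range, size=n_units)
    rates_A = rates_U * rate_mod
    truth = SessionGroundTruth(g_true=g, rates_U=rates_U, rates_A=rates_A,
                               x_loading=x, private_var=private_var)
    C_U, C_A = construct_covariances(truth, window_s)
    unatt = sample_correlated_poisson(
        lam_U, C_U, n_windows, rng, condition="unattended", window_s=window_s)
    att = sample_correlated_poisson(
        rates_A * window_s, C_A, n_windows, rng,
        unit_ids=unatt.unit_ids, condition="attended", window_s=window_s)
    return SessionData(unattended=unatt, attended=att, truth=truth)


# ---------------------------------------------------------------------------
# Text I/O: counts as delimited tables, metadata as a JSON sidecar
# ---------------------------------------------------------------------------

def _write_counts(path: Path, scm: SpikeCountMatrix) -> None:
    df = pd.DataFrame(scm.counts, index=scm.unit_ids,
                      columns=[str(t) for t in range(scm.n_trials)])
    df.to_csv(path, sep="\t", index_label="unit_id")


def _read_counts(path: Path, condition: str, window_s: float) -> SpikeCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="unit_id")
    return SpikeCountMatrix(counts=df.to_numpy(dtype=np.int64),
                            unit_ids=[str(u) for u in df.index],
                            condition=condition, window_s=window_s)


def write_session(directory: str | Path, session: SessionData,
                  seed: int | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_counts(directory / "counts_unattended.tsv", session.unattended)
    _write_counts(directory / "counts_attended.tsv", session.attended)
    meta = {
        "unit_ids": session.unattended.unit_ids,
        "window_s": session.unattended.window_s,
        "seed": seed,
    }
    if session.truth is not None:
        meta["truth"] = {
            "g_true": session.truth.g_true.tolist(),
            "rates_U": session.truth.rates_U.tolist(),
            "rates_A": session.truth.rates_A.tolist(),
            "x_loading": session.truth.x_loading.tolist(),
            "private_var": session.truth.private_var.tolist(),
        }
    (directory / "session.json").write_text(json.dumps(meta, indent=2))


def read_session(directory: str | Path) -> SessionData:
    directory = Path(directory)
    meta = json.loads((directory / "session.json").read_text())
    window_s = float(meta["window_s"])
    unatt = _read_counts(directory / "counts_unattended.tsv",
                         "unattended", window_s)
    att = _read_counts(directory / "counts_attended.tsv",
                       "attended", window_s)
    truth = None
    if "truth" in meta:
        truth = SessionGroundTruth(**{k: np.asarray(v) for k, v in
                                      meta["truth"].items()})
    return SessionData(unattended=unatt, attended=att, truth=truth)
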