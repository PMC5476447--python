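"""Spike-count covariance, noise correlation, and attentional-change stats."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import SpikeCountMatrix

__all__ = [
    "CovarianceEstimate",
    "count_covariance",
    "noise_correlation",
    "normalized_changes",
    "summary_stats",
]


@dataclass
class CovarianceEstimate:
    """Sample covariance of spike counts across trials (spikes^2)."""

    matrix: np.ndarray
    unit_ids: list[str]
    n_trials: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")
        if len(self.unit_ids) != m.shape[0]:
            raise ValueError("unit_ids must match the matrix size")

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    def variances(self) -> np.ndarray:
        return np.diag(self.matrix).copy()


def count_covariance(counts: SpikeCountMatrix) -> CovarianceEstimate:
    """Unbiased (n-1 denominator) covariance of counts across trials."""
    if counts.n_trials < 2:
        raise ValueError("covariance needs at least 2 trials")
    cov = np.cov(counts.counts.astype(float), ddof=1)
    cov = np.atleast_2d(cov)
    return CovarianceEstimate(matrix=0.5 * (cov + cov.T),
                              unit_ids=list(counts.unit_ids),
                              n_trials=counts.n_trials)


def noise_correlation(cov: CovarianceEstimate) -> np.ndarray:
    """Pearson noise-correlation matrix rho_ij = c_ij / sqrt(c_ii c_jj).

    Units with zero variance yield NaN rows/columns (flagged as undefined
    rather than propagated silently); the diagonal is set to 1 wherever it
    is defined.
    """
    v = cov.variances()
    ok = v > 0
    denom = np.sqrt(np.where(ok, v, np.nan))
    rho = cov.matrix / np.outer(denom, denom)
    with np.errstate(invalid="ignore"):
        rho = np.clip(rho, -1.0, 1.0)
    d = np.where(ok, 1.0, np.nan)
    np.fill_diagonal(rho, d)
    return rho


def normalized_changes(C_U: CovarianceEstimate,
                       C_A: CovarianceEstimate) -> tuple[np.ndarray, np.ndarray]:
    """Normalized attentional change of covariance (pairs) and variance (units).

    For each pair i < j the covariance change is
    ``(CovA - CovU) / max(|CovA|, |CovU|)`` and analogously per unit for the
    variances; both are bounded in [-2, 2] by construction.  Entries where
    both values vanish are returned as NaN (undefined).
    """
    if C_U.unit_ids != C_A.unit_ids:
        raise ValueError("unit sets must match")
    iu = np.triu_indices(C_U.n_units, k=1)
    cu, ca = C_U.matrix[iu], C_A.matrix[iu]
    vu, va = C_U.variances(), C_A.variances()

    def _norm(a: np.ndarray, u: np.ndarray) -> np.ndarray:
        denom = np.maximum(np.abs(a), np.abs(u))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, (a - u) / denom, np.nan)
        return out

    return _norm(ca, cu), _norm(va, vu)


def summary_stats(C_U: CovarianceEstimate, C_A: CovarianceEstimate) -> dict:
    """Condition-level summaries (means over defined entries only)."""
    iu = np.triu_indices(C_U.n_units, k=1)
    rho_U = noise_correlation(C_U)[iu]
    rho_A = noise_correlation(C_A)[iu]
    dcov, dvar = normalized_changes(C_U, C_A)
    return {
        "mean_corr_unattended": float(np.nanmean(rho_U)),
        "mean_corr_attended": float(np.nanmean(rho_A)),
        "mean_cov_unattended": float(np.mean(C_U.matrix[iu])),
        "mean_cov_attended": float(np.mean(C_A.matrix[iu])),
        "mean_var_unattended": float(np.mean(C_U.variances())),
        "mean_var_attended": float(np.mean(C_A.variances())),
        "mean_norm_dcov": float(np.nanmean(dcov)),
        "mean_norm_dvar": float(np.nanmean(dvar)),
    }
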