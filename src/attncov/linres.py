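"""Linear-response covariance of an N-neuron network with global input.

A weakly driven recurrent network admits the linear ansatz
``y = y_B + L (J y + xi)`` for trial-to-trial spike counts: background
activity plus gain-scaled recurrent and external input.  When the external
fluctuations are rank one (a single global source with loading x), the
network output covariance inherits that rank:

    C = c c^T,   c = (I - K)^{-1} L x,   K = diag(L) J.

Attention modulates the gains L, so the per-neuron covariance gain is
``g_i = c_i(attended) / c_i(unattended)`` — the circuit-level origin of the
rank-one covariance modulation fitted by :mod:`attncov.rank1`.

For weak coupling (J ~ 1/N) the attentional change of an excitatory
neuron's loading decomposes into a direct term plus excitatory- and
inhibitory-filtered terms; a covariance decrease requires the inhibitory
term to dominate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearNetwork",
    "DecompositionParams",
    "linear_response_rank1",
    "weak_coupling_terms",
]


@dataclass
class LinearNetwork:
    """Signed coupling J (N x N), gains L, global loading x, background b."""

    J: np.ndarray
    L: np.ndarray
    x: np.ndarray
    b: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        n = self.J.shape[0]
        if self.J.shape != (n, n):
            raise ValueError("J must be square")
        if self.L.shape != (n,) or self.x.shape != (n,):
            raise ValueError("L and x must be length-N vectors")
        if self.b is None:
            self.b = np.zeros(n)
        else:
            self.b = np.asarray(self.b, dtype=float)
            if np.any(self.b < 0):
                raise ValueError("background variances must be nonnegative")

    @property
    def K(self) -> np.ndarray:
        return self.L[:, None] * self.J

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.K))))


def linear_response_rank1(net: LinearNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Rank-one output covariance from a shared unit-variance global input.

    Returns the loading vector c = (I - K)^{-1} L x and C = c c^T.  Requires
    the recurrent series to converge (spectral radius of K below one).
    """
    sr = net.spectral_radius()
    if sr >= 1.0:
        raise ValueError(
            f"spectral radius of diag(L) J is {sr:.3f} >= 1; the linear "
            "response is unstable")
    n = net.J.shape[0]
    c = np.linalg.solve(np.eye(n) - net.K, net.L * net.x)
    return c, np.outer(c, c)


@dataclass
class DecompositionParams:
    """E/I composition and gains for the weak-coupling decomposition."""

    q: float            # excitatory fraction
    p: float            # connection probability
    N: int
    J_E: float          # excitatory synaptic magnitude (per synapse)
    J_I: float          # inhibitory synaptic magnitude
    x_E: float
    x_I: float
    L_E_U: float
    L_E_A: float
    L_I_U: float
    L_I_A: float

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def weak_coupling_terms(dp: DecompositionParams) -> dict:
    """Attentional change of an excitatory neuron's covariance loading.

    To first order in the (weak) coupling,

        c_E^A - c_E^U = (L_E^A - L_E^U) x_E                 [direct]
                      + (L_E^A - L_E^U) q p N J_E x_E       [E-filtered]
                      - (L_I^A - L_I^U) (1-q) p N J_I x_I   [I-filtered]

    Attention increases gains, so the first two terms are positive; the
    covariance can only decrease if the inhibitory-filtered term outweighs
    them.
    """
    dLE = dp.L_E_A - dp.L_E_U
    dLI = dp.L_I_A - dp.L_I_U
    direct = dLE * dp.x_E
    e_filtered = dLE * dp.q * dp.p * dp.N * dp.J_E * dp.x_E
    i_filtered = dLI * (1.0 - dp.q) * dp.p * dp.N * dp.J_I * dp.x_I
    total = direct + e_filtered - i_filtered
    return {
        "direct": direct,
        "e_filtered": e_filtered,
        "i_filtered": i_filtered,
        "total": total,
        "inhibition_dominates": bool(i_filtered > direct + e_filtered),
    }
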