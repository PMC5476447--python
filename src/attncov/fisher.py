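"""Linear Fisher information of the E-I population about the stimulus.

The linear Fisher information of the two-population readout is

    FI_EI = G^T C^{-1} G,

with G = (G_E, G_I) the stimulus-response gains and C the long-window
covariance of the population rates.  Because the gains and the noise pass
through the same linearized circuit, the gain matrices cancel and FI_EI
reduces to a closed form in the feedforward gains and input-noise
parameters only,

    FI_EI = (2 chi k_E k_I s_E s_I - k_E^2 s_I^2 - k_I^2 s_E^2)
            / ((chi^2 - 1) s_I^2 s_E^2),

independent of the operating point and hence invariant under attention.
It diverges as chi -> 1 (fully common noise can be cancelled perfectly).

Restricting the readout to the excitatory population gives
FI_E = G_E^2 / V_E, which is attention-dependent: the gain rises and the
excitatory variance falls, so FI_E increases with attention even though
the total information does not.  The uncoupled single-population benchmark
is FI_uc = k_E^2 / sigma_E^2 (the transfer slope cancels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meanfield import Equilibrium, MeanFieldParams, stationary_stats

__all__ = [
    "FisherResult",
    "fisher_total",
    "fisher_total_closed_form",
    "fisher_excitatory",
    "fisher_excitatory_closed_form_chi1",
    "fisher_uncoupled",
    "fisher_report",
]


@dataclass
class FisherResult:
    FI_EI: float
    FI_E: float
    FI_uc: float
    chi: float


def fisher_total_closed_form(k_E: float, k_I: float, sigma_E: float,
                             sigma_I: float, chi: float) -> float:
    if chi >= 1.0:
        raise ZeroDivisionError(
            "chi = 1 makes the population covariance singular (perfect "
            "common-noise cancellation, infinite informational content)")
    num = (2.0 * chi * k_E * k_I * sigma_E * sigma_I
           - k_E ** 2 * sigma_I ** 2 - k_I ** 2 * sigma_E ** 2)
    den = (chi ** 2 - 1.0) * sigma_I ** 2 * sigma_E ** 2
    return num / den


def fisher_total(eq: Equilibrium, p: MeanFieldParams,
                 check_tol: float = 1e-10) -> float:
    """FI_EI from the matrix form, cross-checked against the closed form.

    Requires chi < 1; the matrix route inverts the long-window covariance
    of (r_E, r_I) and contracts it with the stimulus gains.
    """
    if p.chi >= 1.0:
        raise ZeroDivisionError(
            "chi = 1 makes the population covariance singular")
    stats = stationary_stats(eq, p)
    C = np.array([[stats.V_E, stats.C_EI], [stats.C_EI, stats.V_I]])
    if abs(np.linalg.det(C)) < 1e-300:
        raise ArithmeticError("population covariance is singular")
    G = np.array([stats.G_E, stats.G_I])
    fi = float(G @ np.linalg.solve(C, G))
    closed = fisher_total_closed_form(p.k_E, p.k_I, p.sigma_E, p.sigma_I,
                                      p.chi)
    if abs(fi - closed) > check_tol * max(abs(closed), 1.0):
        raise ArithmeticError(
            f"matrix-form FI_EI ({fi!r}) disagrees with the closed form "
            f"({closed!r})")
    return fi


def fisher_excitatory(eq: Equilibrium, p: MeanFieldParams) -> float:
    """Excitatory-readout information FI_E = G_E^2 / V_E (general chi)."""
    stats = stationary_stats(eq, p)
    if stats.V_E <= 0:
        raise ArithmeticError("excitatory variance is zero; FI_E undefined")
    return stats.G_E ** 2 / stats.V_E


def fisher_excitatory_closed_form_chi1(L_I: float, J_I: float, k_E: float,
                                       k_I: float, sigma_E: float,
                                       sigma_I: float) -> float:
    """Closed form for FI_E with symmetric coupling and fully common noise.

    Expanding G_E^2 / V_E (the shared gain factor L_E and the denominator
    1 + J_I L_I - J_E L_E cancel):

        FI_E = (k_E + J_I L_I (k_E - k_I))^2
               / (J_I L_I (sigma_E - sigma_I) + sigma_E)^2.
    """
    num = (k_E + J_I * L_I * (k_E - k_I)) ** 2
    den = (J_I * L_I * (sigma_E - sigma_I) + sigma_E) ** 2
    return num / den


def fisher_uncoupled(k_E: float, sigma_E: float) -> float:
    """Uncoupled benchmark k_E^2 / sigma_E^2 (transfer slope cancels)."""
    if sigma_E == 0:
        raise ZeroDivisionError("sigma_E = 0 gives divergent information")
    return k_E ** 2 / sigma_E ** 2


def fisher_report(eq: Equilibrium, p: MeanFieldParams) -> FisherResult:
    return FisherResult(
        FI_EI=fisher_total(eq, p),
        FI_E=fisher_excitatory(eq, p),
        FI_uc=fisher_uncoupled(p.k_E, p.sigma_E),
        chi=p.chi,
    )
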