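"""Closed-form solutions of the spatially lumped kinetics.

Under a constant oxygen level the spatial structure decouples from the
total (space-integrated) masses, and the lumped kinetics admit closed
forms that serve as verification oracles for the PDE solver:

* sustained hypoxia (``c_N < c < c_H``): normoxic mass decays
  exponentially into the hypoxic compartment at rate ``mu_nh`` while the
  total is conserved;
* sustained normoxia (``c > c_H``): no hypoxic cells ever appear and the
  normoxic density follows a logistic law toward the space left free by
  the (undegraded) ECM.

A third closed form gives the stable equilibrium of the phenotype drift
under sustained hypoxia, ``mu* = mu_hn0 - alpha * (1 - c2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ModelParameters

__all__ = [
    "LumpedSolution",
    "analytic_hypoxic_decay",
    "analytic_normoxic_logistic",
    "hypoxic_equilibrium_phenotype",
]


@dataclass(frozen=True)
class LumpedSolution:
    """Total masses of the lumped model at times ``t``."""

    t: np.ndarray
    n_tot: np.ndarray
    h_tot: np.ndarray
    e_tot: float


def analytic_hypoxic_decay(t, N0: float, mu_nh: float) -> LumpedSolution:
    """Sustained-hypoxia totals: ``n_tot = N0 exp(-mu_nh t)``.

    The hypoxic mass is the complement ``N0 (1 - exp(-mu_nh t))``;
    ``n_tot + h_tot = N0`` for all t (transitions conserve cells, and no
    growth or death is active between the thresholds).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if N0 < 0:
        raise ValueError("N0 must be >= 0")
    n_tot = N0 * np.exp(-mu_nh * t)
    return LumpedSolution(t=t, n_tot=n_tot, h_tot=N0 - n_tot, e_tot=np.nan)


def analytic_normoxic_logistic(t, N0: float, e_tot: float,
                               lambda_n: float) -> LumpedSolution:
    """Sustained-normoxia totals: logistic growth toward ``1 - e_tot``.

        n_tot(t) = (1 - e_tot) / (1 + ((1 - N0 - e_tot)/N0) exp(-lambda_n (1 - e_tot) t))

    ECM is never degraded (no hypoxic cells), so ``e_tot`` is constant and
    caps the carrying capacity.  ``N0 = 0`` is the degenerate fixed point:
    the solution is identically zero.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if N0 < 0 or e_tot < 0 or N0 + e_tot > 1 + 1e-12:
        raise ValueError("need 0 <= N0, 0 <= e_tot, N0 + e_tot <= 1")
    if N0 == 0.0:
        n_tot = np.zeros_like(t)
    else:
        cap = 1.0 - e_tot
        n_tot = cap / (1.0 + ((1.0 - N0 - e_tot) / N0)
                       * np.exp(-lambda_n * cap * t))
    return LumpedSolution(t=t, n_tot=n_tot, h_tot=np.zeros_like(t),
                          e_tot=e_tot)


def hypoxic_equilibrium_phenotype(c2: float, params: ModelParameters) -> float:
    """Stable zero of the trait velocity under sustained oxygen ``c2``.

    Returns ``mu* = mu_hn0 - alpha * (1 - c2)``; the velocity is negative
    above and positive below, so all hypoxic mass drifts there under
    prolonged hypoxia.  A non-positive result violates the modelling
    requirement that a minimal positive transition rate be attained, and
    raises.
    """
    if c2 >= params.c_H:
        raise ValueError("equilibrium phenotype is defined for hypoxic c2 < c_H")
    mu_star = params.mu_hn0 - params.alpha * (1.0 - c2)
    if mu_star <= 0:
        raise ValueError(
            f"equilibrium phenotype {mu_star:.4g} <= 0: alpha too strong "
            f"for oxygen level {c2}")
    return mu_star
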