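"""Model parameters, oxygen protocol, and pointwise kinetics.

Dimensionless phenotype-structured model of tumor invasion under a
time-switched oxygen environment.  Three fields interact: normoxic cells
``n(x, t)``, hypoxic cells ``h(x, t, mu)`` structured by the phenotype
coordinate ``mu`` in ``[0, 1]`` (the hypoxic-to-normoxic transition rate),
and extracellular matrix ``e(x, t)``.  Oxygen ``c(t)`` is spatially
homogeneous and switches between a normoxic level ``c1`` and a hypoxic
level ``c2``.

All rate terms are gated by Heaviside switches on the oxygen level
relative to the hypoxic threshold ``c_H`` and the necrotic threshold
``c_N``; the convention ``H(0) = 0`` is used throughout, so the exact
threshold ``c = c_H`` counts as the normoxic side for gating and for the
memory timescale.

Hypoxic memory enters through an advection velocity in phenotype space,

    v(mu, c) = -(alpha * (1 - c) + mu - mu_hn0) / beta,

which drifts hypoxic cells toward lower transition rates (stronger
memory) under hypoxia and relaxes them back toward the basal rate
``mu_hn0`` under normoxia.  ``beta`` switches between an induction
timescale ``beta_l`` (active while ``c < c_H``) and a slower erasure
timescale ``beta_h`` (active while ``c >= c_H``).  Setting ``alpha = 0``
removes the oxygen dependence entirely: the memoryless limit, in which
all hypoxic mass stays at the injection coordinate ``mu_hn0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ModelParameters",
    "OxygenProtocol",
    "oxygen_at",
    "select_beta",
    "phenotype_velocity",
    "heaviside_gates",
    "reaction_normoxic",
    "reaction_hypoxic_local",
    "integrated_H",
    "phenotype_first_moment",
    "validate_memory_feasibility",
]


@dataclass(frozen=True)
class ModelParameters:
    """Dimensionless rate and threshold constants of the model.

    Defaults are the reference parameterization used throughout the
    experiment suite.

    Attributes
    ----------
    D_h : float
        Hypoxic-cell diffusivity.
    xi_h : float
        Haptotaxis coefficient (drift up ECM gradients).
    lambda_n : float
        Normoxic proliferation rate.
    mu_nh : float
        Normoxic-to-hypoxic transition rate (active under hypoxia).
    mu_hn0 : float
        Basal hypoxic-to-normoxic transition rate; also the phenotype
        coordinate at which freshly converted hypoxic cells are injected.
    gamma_n, gamma_h : float
        Necrotic death rates of normoxic / hypoxic cells (below ``c_N``).
    delta : float
        ECM degradation rate by hypoxic cells.
    c_H : float
        Hypoxic oxygen threshold (dimensionless, scaled by the normoxic
        level).
    c_N : float
        Necrotic oxygen threshold.
    alpha : float
        Strength of memory induction; ``alpha = 0`` is the memoryless
        limit.
    beta_l : float
        Memory-induction timescale, active while ``c < c_H``.
    beta_h : float
        Memory-erasure timescale, active while ``c >= c_H``.
    """

    D_h: float = 0.01
    xi_h: float = 0.001
    lambda_n: float = 0.1
    mu_nh: float = 0.5
    mu_hn0: float = 0.5
    gamma_n: float = 0.001
    gamma_h: float = 0.001
    delta: float = 15.0
    c_H: float = 0.5
    c_N: float = 0.1
    alpha: float = 0.8
    beta_l: float = 2.0
    beta_h: float = 20.0

    def __post_init__(self) -> None:
        for name in ("D_h", "xi_h", "lambda_n", "mu_nh", "gamma_n",
                     "gamma_h", "delta", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.beta_l <= 0 or self.beta_h <= 0:
            raise ValueError("memory timescales beta_l, beta_h must be > 0")
        if not (0.0 <= self.c_N < self.c_H <= 1.0):
            raise ValueError("thresholds must satisfy 0 <= c_N < c_H <= 1")
        if not (0.0 < self.mu_hn0 <= 1.0):
            raise ValueError("mu_hn0 must lie inside the phenotype domain (0, 1]")

    def memoryless(self) -> "ModelParameters":
        """Return a copy with ``alpha = 0`` (no hypoxic memory)."""
        d = asdict(self)
        d["alpha"] = 0.0
        return ModelParameters(**d)


@dataclass(frozen=True)
class OxygenProtocol:
    """Piecewise-constant-in-time, spatially homogeneous oxygen schedule.

    In cyclic mode each cycle of length ``period`` starts with a normoxic
    phase at ``c1`` lasting ``(1 - bias) * period``, followed by a hypoxic
    phase at ``c2``; ``bias`` is the fraction of the cycle spent hypoxic.
    Intervals are left-open / right-closed, so the instant a phase ends
    still belongs to it; ``t = 0`` is taken as the top of the first
    normoxic phase.  Constant mode holds a fixed ``level`` (Case I/II
    verification runs).
    """

    c1: float = 1.0
    c2: float = 0.4
    period: float = 10.0
    bias: float = 0.5
    t_final: float = 60.0
    mode: str = "cyclic"
    level: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.mode not in ("cyclic", "constant"):
            raise ValueError("mode must be 'cyclic' or 'constant'")
        if self.t_final < 0:
            raise ValueError("t_final must be >= 0")
        if self.mode == "cyclic":
            if self.period <= 0:
                raise ValueError("period must be > 0")
            if not (0.0 < self.bias < 1.0):
                raise ValueError("bias must lie strictly between 0 and 1")
            if not (self.c2 < self.c1):
                raise ValueError("cyclic protocol needs c2 < c1")
        else:
            if not np.isfinite(self.level):
                raise ValueError("constant mode requires a finite level")

    @classmethod
    def constant(cls, level: float, t_final: float = 60.0) -> "OxygenProtocol":
        return cls(mode="constant", level=level, t_final=t_final)

    def levels(self) -> tuple[float, ...]:
        """Oxygen levels visited over the whole run (for CFL bounds)."""
        if self.mode == "constant":
            return (self.level,)
        return (self.c1, self.c2)


def oxygen_at(protocol: OxygenProtocol, t: float) -> float:
    """Oxygen concentration at time ``t``.

    Cyclic mode: ``c1`` on the normoxic sub-interval ``(0, (1-bias)*period]``
    of each cycle, ``c2`` on the remainder; cycle boundaries (``t`` an exact
    multiple of the period) belong to the preceding hypoxic phase, except
    ``t = 0`` which starts normoxic.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if protocol.mode == "constant":
        return protocol.level
    if t == 0.0:
        return protocol.c1
    s = t % protocol.period
    if s == 0.0:  # exact end of a full cycle -> end of hypoxic phase
        return protocol.c2
    t_normoxic = (1.0 - protocol.bias) * protocol.period
    return protocol.c1 if s <= t_normoxic else protocol.c2


def select_beta(c: float, params: ModelParameters) -> float:
    """Memory timescale active at oxygen level ``c``.

    Induction (``beta_l``) under hypoxia ``c < c_H``; erasure (``beta_h``)
    otherwise.  The tie ``c = c_H`` follows the Heaviside convention
    ``H(0) = 0`` and counts as the normoxic side.
    """
    if c < 0:
        raise ValueError("oxygen level must be >= 0")
    return params.beta_l if c < params.c_H else params.beta_h


def phenotype_velocity(mu, c: float, params: ModelParameters,
                       beta: float | None = None):
    """Drift velocity in phenotype space, ``-(alpha(1-c) + mu - mu_hn0)/beta``.

    ``mu`` may be a scalar or an array.  ``beta`` defaults to
    :func:`select_beta` at the given oxygen level.
    """
    if beta is None:
        beta = select_beta(c, params)
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return -(params.alpha * (1.0 - c) + np.asarray(mu) - params.mu_hn0) / beta


def heaviside_gates(c: float, params: ModelParameters) -> tuple[float, float, float]:
    """The three Heaviside switches ``(H(c-c_H), H(c_H-c), H(c_N-c))``.

    ``H(0) = 0`` exactly, so at ``c = c_H`` both transition gates are off.
    """
    g_norm = 1.0 if c > params.c_H else 0.0
    g_hyp = 1.0 if c < params.c_H else 0.0
    g_nec = 1.0 if c < params.c_N else 0.0
    return g_norm, g_hyp, g_nec


def reaction_normoxic(n, H, e, phenotype_first_moment, c: float,
                      params: ModelParameters):
    """Pointwise rate of change of the normoxic density.

    Four gated terms: volume-limited logistic proliferation (normoxia),
    gain from hypoxic cells escaping at their phenotype-dependent rate
    (normoxia; ``phenotype_first_moment`` is the caller-supplied
    ``integral of mu * h dmu``), loss to the hypoxic compartment
    (hypoxia), and necrosis (below ``c_N``).
    """
    g_norm, g_hyp, g_nec = heaviside_gates(c, params)
    n = np.asarray(n, dtype=float)
    return (params.lambda_n * n * (1.0 - n - H - e) * g_norm
            + np.asarray(phenotype_first_moment) * g_norm
            - params.mu_nh * n * g_hyp
            - params.gamma_n * n * g_nec)


def reaction_hypoxic_local(h_at_mu, mu, n, c: float, is_injection_node,
                           dmu: float, params: ModelParameters):
    """Pointwise rate of change of ``h`` at one ``(x, mu)`` from reactions.

    Injection of freshly converted normoxic cells happens only at the
    node carrying the basal coordinate ``mu_hn0`` and is scaled by
    ``1/dmu`` so that its mu-integral equals the normoxic loss
    ``mu_nh * n`` exactly — ``h`` is a density over the phenotype
    coordinate, and the discrete transition pair must conserve mass.
    Escape back to normoxia proceeds at rate ``mu`` (the phenotype
    coordinate itself) while ``c > c_H``; necrosis at rate ``gamma_h``
    below ``c_N``.
    """
    mu = np.asarray(mu, dtype=float)
    inj = np.asarray(is_injection_node, dtype=bool)
    if np.any(inj & (np.abs(mu - params.mu_hn0) > 0.5 * dmu)):
        raise ValueError("injection node flagged away from mu_hn0")
    g_norm, g_hyp, g_nec = heaviside_gates(c, params)
    h_at_mu = np.asarray(h_at_mu, dtype=float)
    gain = np.where(inj, params.mu_nh * np.asarray(n) / dmu * g_hyp, 0.0)
    return gain - mu * h_at_mu * g_norm - params.gamma_h * h_at_mu * g_nec


def integrated_H(h, dmu: float):
    """Total hypoxic density ``H = integral of h dmu`` (rectangle rule).

    ``h`` has the phenotype coordinate on its last axis.  The rectangle
    rule (plain node sum times ``dmu``) is used for every mu-integral in
    the package so that the discrete transition terms conserve mass
    exactly.
    """
    return np.asarray(h).sum(axis=-1) * dmu


def phenotype_first_moment(h, mu_nodes, dmu: float):
    """First phenotype moment ``integral of mu * h dmu`` (rectangle rule)."""
    return (np.asarray(h) * np.asarray(mu_nodes)).sum(axis=-1) * dmu


def validate_memory_feasibility(params: ModelParameters,
                                protocol: OxygenProtocol) -> None:
    """Check that the memory equilibrium phenotype stays positive.

    Under sustained oxygen at the protocol's lowest level ``c_low`` the
    drift settles at ``mu* = mu_hn0 - alpha * (1 - c_low)``; the model
    requires a minimal *positive* transition rate to be attained, so
    ``mu* <= 0`` is a configuration error (alpha too strong for the
    hypoxic level).
    """
    if params.alpha == 0:
        return
    c_low = min(protocol.levels())
    mu_star = params.mu_hn0 - params.alpha * (1.0 - c_low)
    if mu_star <= 0:
        raise ValueError(
            f"alpha={params.alpha} drives the equilibrium phenotype to "
            f"{mu_star:.4g} <= 0 at oxygen level {c_low}; reduce alpha or "
            "raise the hypoxic level")
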