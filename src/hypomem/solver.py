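"""Explicit method-of-lines discretization on the space x phenotype mesh.

The 1D physical domain ``[0, X]`` and the phenotype domain ``[0, 1]`` are
covered by uniform node-centered meshes.  Spatial transport of hypoxic
cells (volume-filling diffusion plus haptotaxis up ECM gradients) is
discretized in conservative flux form with face-averaged coefficients;
trait drift uses first-order donor-cell upwinding with the (linear in mu)
velocity evaluated exactly at cell faces.  Both transports carry zero
flux through the domain boundaries, so the per-x phenotype mass and the
spatially integrated mass are preserved by transport to machine
precision.  Time integration is forward Euler under a CFL bound combining
the diffusive limit ``dx^2 / (2 D_h)`` and the advective limit
``dmu / f_max``, with ``f_max`` the largest trait speed attainable over
the whole run (both oxygen levels, whole phenotype interval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import cached_property

import numpy as np

from .core import (
    ModelParameters,
    OxygenProtocol,
    oxygen_at,
    phenotype_velocity,
    heaviside_gates,
    integrated_H,
    phenotype_first_moment,
    validate_memory_feasibility,
)

__all__ = [
    "Grids",
    "TumorState",
    "SolverSettings",
    "InitialCondition",
    "ScenarioConfig",
    "Trajectory",
    "initialize_state",
    "max_trait_speed",
    "cfl_timestep",
    "spatial_flux_update",
    "phenotype_advection_update",
    "step",
    "simulate",
]

#: negativity below this magnitude is clipped to zero; anything larger
#: aborts the run as a stability/implementation failure.
NEGATIVITY_TOL = 1e-12


@dataclass(frozen=True)
class Grids:
    """Uniform meshes on ``[0, X]`` (space) and ``[0, 1]`` (phenotype).

    The phenotype mesh must contain the injection coordinate ``mu_hn0``
    as an exact node; this is validated at construction.
    """

    X: float = 10.0
    N: int = 201
    M: int = 101
    mu_hn0: float = 0.5

    def __post_init__(self) -> None:
        if self.N < 3 or self.M < 3:
            raise ValueError("need at least 3 nodes per axis")
        if self.X <= 0:
            raise ValueError("X must be > 0")
        j = round(self.mu_hn0 / self.dmu)
        if not (0 <= j < self.M) or abs(j * self.dmu - self.mu_hn0) > 1e-12:
            raise ValueError(
                f"phenotype mesh (M={self.M}) has no node at mu_hn0={self.mu_hn0}")

    @property
    def dx(self) -> float:
        return self.X / (self.N - 1)

    @property
    def dmu(self) -> float:
        return 1.0 / (self.M - 1)

    @property
    def injection_index(self) -> int:
        return round(self.mu_hn0 / self.dmu)

    @cached_property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.X, self.N)

    @cached_property
    def mu(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.M)

    @cached_property
    def mu_faces(self) -> np.ndarray:
        """Interior face coordinates ``(j + 1/2) * dmu``, j = 0..M-2."""
        return 0.5 * (self.mu[:-1] + self.mu[1:])

    def refined(self, factor: int = 2) -> "Grids":
        """Grid with ``dx`` and ``dmu`` divided by ``factor``."""
        return Grids(X=self.X, N=factor * (self.N - 1) + 1,
                     M=factor * (self.M - 1) + 1, mu_hn0=self.mu_hn0)


@dataclass
class TumorState:
    """Fields at one instant: ``n(x)``, ``h(x, mu)``, ``e(x)``.

    ``clipped`` counts entries that were clipped to zero (from within the
    negativity tolerance) while producing this state.
    """

    t: float
    n: np.ndarray
    h: np.ndarray
    e: np.ndarray
    clipped: int = 0

    def H(self, dmu: float) -> np.ndarray:
        return integrated_H(self.h, dmu)

    def copy(self) -> "TumorState":
        return TumorState(self.t, self.n.copy(), self.h.copy(),
                          self.e.copy(), self.clipped)


@dataclass(frozen=True)
class SolverSettings:
    """Time-stepping and recording controls.

    ``f_max`` is derived from the scenario (largest trait-advection
    speed), never user-set; ``None`` means "compute it".
    """

    cfl_safety: float = 0.9
    output_every: float = 0.1
    snapshot_times: tuple[float, ...] = ()
    f_max: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.cfl_safety <= 1.0):
            raise ValueError("cfl_safety must lie in (0, 1]")
        if self.output_every <= 0:
            raise ValueError("output_every must be > 0")


@dataclass(frozen=True)
class InitialCondition:
    """Step-profile initial data: normoxic tumor on ``[a, b]``, ECM outside."""

    n0: float = 0.5
    e0: float = 0.5
    a: float = 4.0
    b: float = 6.0

    def __post_init__(self) -> None:
        if self.a >= self.b:
            raise ValueError("need a < b")
        if self.n0 < 0 or self.e0 < 0:
            raise ValueError("densities must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one run; simulate() is a pure function of it."""

    params: ModelParameters = field(default_factory=ModelParameters)
    protocol: OxygenProtocol = field(default_factory=OxygenProtocol)
    grids: Grids | None = None
    settings: SolverSettings = field(default_factory=SolverSettings)
    ic: InitialCondition = field(default_factory=InitialCondition)

    def resolved_grids(self) -> Grids:
        if self.grids is not None:
            return self.grids
        return Grids(mu_hn0=self.params.mu_hn0)

    def echo(self) -> dict:
        """Plain-dict image of the full configuration (for provenance)."""
        d = {
            "params": asdict(self.params),
            "protocol": asdict(self.protocol),
            "grids": asdict(self.resolved_grids()),
            "settings": asdict(self.settings),
            "ic": asdict(self.ic),
        }
        d["settings"]["snapshot_times"] = list(self.settings.snapshot_times)
        return d


@dataclass
class Trajectory:
    """Time-indexed record of one run.

    Scalar-observable inputs (``n``, ``H``, ``e`` profiles) are recorded
    every ``output_every``; full phenotype-resolved snapshots only at the
    configured ``snapshot_times``.
    """

    times: np.ndarray            # (R,)
    n_xt: np.ndarray             # (R, N)
    H_xt: np.ndarray             # (R, N)
    e_xt: np.ndarray             # (R, N)
    snapshots: list              # [(t, TumorState), ...]
    final_state: TumorState
    grids: Grids
    config: dict                 # config echo
    dt: float
    clipped: int = 0

    @property
    def total_xt(self) -> np.ndarray:
        return self.n_xt + self.H_xt

    def mass_totals(self) -> dict[str, np.ndarray]:
        dx = self.grids.dx
        return {
            "n_tot": self.n_xt.sum(axis=1) * dx,
            "h_tot": self.H_xt.sum(axis=1) * dx,
            "e_tot": self.e_xt.sum(axis=1) * dx,
        }


def initialize_state(grids: Grids, ic: InitialCondition = InitialCondition()
                     ) -> TumorState:
    """Build the t = 0 state: all-normoxic step tumor, ECM elsewhere, no h."""
    x = grids.x
    inside = (x >= ic.a - 1e-9) & (x <= ic.b + 1e-9)
    n = np.where(inside, ic.n0, 0.0)
    e = np.where(inside, 0.0, ic.e0)
    h = np.zeros((grids.N, grids.M))
    return TumorState(t=0.0, n=n, h=h, e=e)


def max_trait_speed(params: ModelParameters, protocol: OxygenProtocol) -> float:
    """Worst-case |trait velocity| over mu in [0, 1] and all oxygen levels.

    The velocity is linear in mu, so its extremes sit at mu = 0 and 1.
    In the memoryless limit (alpha = 0) every hypoxic cell sits at the
    stationary coordinate ``mu_hn0`` forever, so the advection bound is
    vacuous and 0 is returned.
    """
    if params.alpha == 0.0:
        return 0.0
    speeds = [abs(float(phenotype_velocity(m, c, params)))
              for c in protocol.levels() for m in (0.0, 1.0)]
    return max(speeds)


def cfl_timestep(grids: Grids, params: ModelParameters,
                 protocol: OxygenProtocol,
                 settings: SolverSettings = SolverSettings()) -> float:
    """Stability-limited timestep for the explicit scheme.

    ``cfl_safety`` times the smallest of three bounds: the diffusive
    limit ``dx^2 / (2 D_h)``, the trait-advection limit ``dmu / f_max``,
    and a positivity limit ``1 / r_max`` for the pointwise decay terms,
    where ``r_max`` is the largest decay rate any field can experience
    (ECM degradation ``delta * H`` with ``H <= 1`` by volume filling,
    the transition rates, the escape rate ``mu <= 1``, and necrosis).
    The decay bound keeps forward Euler from overshooting a decaying
    field below zero when the transport bounds are loose (coarse grids
    or the memoryless limit).
    """
    f_max = settings.f_max
    if f_max is None:
        f_max = max_trait_speed(params, protocol)
    bounds = []
    if params.D_h > 0:
        bounds.append(grids.dx ** 2 / (2.0 * params.D_h))
    if f_max > 0:
        bounds.append(grids.dmu / f_max)
    r_max = max(params.delta, params.mu_nh, 1.0,
                params.gamma_n, params.gamma_h)
    bounds.append(1.0 / r_max)
    return settings.cfl_safety * min(bounds)


def spatial_flux_update(state: TumorState, params: ModelParameters,
                        grids: Grids) -> np.ndarray:
    """Rate of change of ``h`` from diffusion + haptotaxis (flux form).

    Face flux at ``i + 1/2``:

        D_h * (1 - n - H - e)_{i+1/2} * (h_{i+1} - h_i)/dx
        - xi_h * h_{i+1/2} * (e_{i+1} - e_i)/dx

    with arithmetic face averages.  The total flux through ``x = 0`` and
    ``x = X`` is zero (no-flux boundary on the combined transport).
    """
    h, n, e = state.h, state.n, state.e
    phi = 1.0 - n - state.H(grids.dmu) - e          # motility-limiting factor
    dx = grids.dx
    coef = params.D_h * 0.5 * (phi[:-1] + phi[1:])  # (N-1,)
    diff_flux = coef[:, None] * (h[1:, :] - h[:-1, :]) / dx
    hap_flux = (params.xi_h * 0.5 * (h[1:, :] + h[:-1, :])
                * ((e[1:] - e[:-1]) / dx)[:, None])
    flux = diff_flux - hap_flux                     # (N-1, M) interior faces
    out = np.empty_like(h)
    out[0, :] = flux[0, :] / dx                     # face -1/2 carries zero
    out[-1, :] = -flux[-1, :] / dx                  # face N-1/2 carries zero
    out[1:-1, :] = (flux[1:, :] - flux[:-1, :]) / dx
    return out


def phenotype_advection_update(state: TumorState, c: float,
                               params: ModelParameters,
                               grids: Grids) -> np.ndarray:
    """Rate of change of ``h`` from trait drift, ``-d(v h)/dmu``.

    Conservative donor-cell upwind: the face flux is ``v_face * h_donor``
    with the donor chosen by the sign of the face velocity; convective
    flux through ``mu = 0`` and ``mu = 1`` is zero, so the per-x phenotype
    mass is exactly preserved.
    """
    h = state.h
    v_face = np.asarray(phenotype_velocity(grids.mu_faces, c, params))
    donor = np.where(v_face > 0, h[:, :-1], h[:, 1:])
    flux = v_face * donor                            # (N, M-1) interior faces
    out = np.empty_like(h)
    out[:, 0] = -flux[:, 0] / grids.dmu
    out[:, -1] = flux[:, -1] / grids.dmu
    out[:, 1:-1] = -(flux[:, 1:] - flux[:, :-1]) / grids.dmu
    return out


def step(state: TumorState, protocol: OxygenProtocol,
         params: ModelParameters, grids: Grids, dt: float) -> TumorState:
    """One forward-Euler step of the full coupled system.

    Oxygen is sampled at the current time.  Raises on NaNs or on
    negativity beyond ``NEGATIVITY_TOL`` (a CFL or implementation
    failure); negativity within tolerance is clipped to zero and counted.
    """
    c = oxygen_at(protocol, state.t)
    g_norm, g_hyp, g_nec = heaviside_gates(c, params)
    dmu = grids.dmu
    n, h, e = state.n, state.h, state.e
    H = state.H(dmu)
    moment = phenotype_first_moment(h, grids.mu, dmu)

    # normoxic cells (pointwise reactions only; normoxic cells do not move)
    dn = (params.lambda_n * n * (1.0 - n - H - e) * g_norm
          + moment * g_norm
          - params.mu_nh * n * g_hyp
          - params.gamma_n * n * g_nec)

    # hypoxic cells: transport + trait drift + gated reactions
    dh = spatial_flux_update(state, params, grids)
    dh += phenotype_advection_update(state, c, params, grids)
    if g_norm:
        dh -= grids.mu[None, :] * h * g_norm
    if g_hyp:
        dh[:, grids.injection_index] += params.mu_nh * n / dmu
    if g_nec:
        dh -= params.gamma_h * h

    n_new = n + dt * dn
    h_new = h + dt * dh
    e_new = e * (1.0 - params.delta * dt * H)

    clipped = state.clipped
    arrays = (n_new, h_new, e_new)
    for arr in arrays:
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(
                f"non-finite field at t={state.t:.6g} (dt={dt:.3g})")
        m = arr.min()
        if m < -NEGATIVITY_TOL:
            raise FloatingPointError(
                f"negativity {m:.3e} beyond tolerance at t={state.t:.6g}; "
                "CFL bound or scheme violated")
        if m < 0.0:
            neg = arr < 0.0
            clipped += int(neg.sum())
            arr[neg] = 0.0

    return TumorState(t=state.t + dt, n=n_new, h=h_new, e=e_new,
                      clipped=clipped)


def simulate(config: ScenarioConfig) -> Trajectory:
    """Run a scenario from t = 0 to ``protocol.t_final``.

    Deterministic: identical configs produce bit-identical trajectories.
    The step count is chosen so that the CFL-limited step divides
    ``t_final`` exactly; profiles feeding the scalar observables are
    recorded about every ``output_every`` time units (always including
    t = 0 and t_final), and full ``h(x, mu)`` snapshots at the first step
    reaching each requested snapshot time.
    """
    params, protocol = config.params, config.protocol
    grids = config.resolved_grids()
    settings = config.settings
    if protocol.mode == "cyclic" and not (protocol.c2 < params.c_H < protocol.c1):
        raise ValueError("cyclic protocol must straddle the hypoxic threshold")
    validate_memory_feasibility(params, protocol)

    state = initialize_state(grids, config.ic)
    t_final = protocol.t_final

    # record (t, n, H, e) — integrate h out immediately so full phenotype
    # fields are only retained for explicitly requested snapshots
    records: list[tuple[float, np.ndarray, np.ndarray, np.ndarray]] = []
    snapshots: list[tuple[float, TumorState]] = []

    def record(s: TumorState) -> None:
        records.append((s.t, s.n.copy(), s.H(grids.dmu), s.e.copy()))

    record(state)
    if t_final == 0.0:
        dt = 0.0
        nsteps = 0
    else:
        dt_max = cfl_timestep(grids, params, protocol, settings)
        nsteps = max(1, math.ceil(t_final / dt_max))
        dt = t_final / nsteps
    stride = max(1, round(settings.output_every / dt)) if nsteps else 1

    snap_times = sorted(settings.snapshot_times)
    snap_ptr = 0
    # requested snapshot at t=0
    while snap_ptr < len(snap_times) and snap_times[snap_ptr] <= 1e-12:
        snapshots.append((0.0, state.copy()))
        snap_ptr += 1

    for k in range(1, nsteps + 1):
        state = step(state, protocol, params, grids, dt)
        state.t = k * dt  # avoid accumulated summation drift
        if k % stride == 0 or k == nsteps:
            record(state)
        while (snap_ptr < len(snap_times)
               and state.t >= snap_times[snap_ptr] - 1e-9):
            snapshots.append((state.t, state.copy()))
            snap_ptr += 1

    times = np.array([r[0] for r in records])
    n_xt = np.stack([r[1] for r in records])
    H_xt = np.stack([r[2] for r in records])
    e_xt = np.stack([r[3] for r in records])
    return Trajectory(times=times, n_xt=n_xt, H_xt=H_xt, e_xt=e_xt,
                      snapshots=snapshots, final_state=state, grids=grids,
                      config=config.echo(), dt=dt, clipped=state.clipped)
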