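"""Summary metrics: tumor boundary, volume, front composition, hitting
times, phenotype (memory) distributions, and divergences.

Conventions shared by every metric:

* the tumor right boundary is the largest ``x`` where the total cell
  density ``n + H`` crosses a small threshold (default 1e-6), located by
  linear interpolation between mesh nodes;
* the tumor front is the band extending ``front_depth`` (default 0.5)
  inward from the right boundary;
* metrics over empty or sub-threshold regions return NaN (an explicit
  "undefined" marker that serializes as missing), never 0;
* spatial integrals use the same rectangle rule as the solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import Trajectory, TumorState

__all__ = [
    "FrontDefinition",
    "PhenotypeDistribution",
    "tumor_right_boundary",
    "boundary_trace",
    "tumor_volume",
    "front_hypoxic_fraction",
    "front_hypoxic_fraction_trace",
    "mean_front_hypoxic_fraction",
    "hitting_time",
    "phenotype_distribution",
    "distribution_from_snapshot",
    "strong_memory_fraction",
    "front_to_bulk_memory_ratio",
    "jensen_shannon_divergence",
    "percent_change",
]


@dataclass(frozen=True)
class FrontDefinition:
    """Edge threshold and front-band depth defining the invasive front."""

    boundary_threshold: float = 1e-6
    front_depth: float = 0.5

    def __post_init__(self) -> None:
        if self.boundary_threshold <= 0 or self.front_depth <= 0:
            raise ValueError("threshold and depth must be > 0")


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Normalized distribution of hypoxic-cell mass over the phenotype mesh."""

    support: np.ndarray
    mass: np.ndarray
    region_label: str = ""
    cycle_label: str = ""

    def __post_init__(self) -> None:
        if self.support.shape != self.mass.shape:
            raise ValueError("support and mass must have matching shapes")
        if np.any(self.mass < -1e-12):
            raise ValueError("distribution weights must be >= 0")
        if abs(self.mass.sum() - 1.0) > 1e-8:
            raise ValueError("distribution weights must sum to 1")

    @property
    def mean(self) -> float:
        return float((self.support * self.mass).sum())


# ---------------------------------------------------------------------------
# boundary, volume, front


def _right_boundary(total: np.ndarray, x: np.ndarray, threshold: float) -> float:
    """Largest crossing of ``total`` through ``threshold``, interpolated."""
    above = np.flatnonzero(total >= threshold)
    if above.size == 0:
        return float(x[0])
    i = above[-1]
    if i == len(x) - 1:
        return float(x[-1])
    f0, f1 = total[i], total[i + 1]
    # linear interpolation; f1 < threshold <= f0 by construction
    return float(x[i] + (x[i + 1] - x[i]) * (threshold - f0) / (f1 - f0))


def tumor_right_boundary(state: TumorState, grids,
                         frontdef: FrontDefinition = FrontDefinition()) -> float:
    """Rightmost position where ``n + H`` reaches the edge threshold.

    Returns the domain's left edge if the tumor is entirely below
    threshold.
    """
    total = state.n + state.H(grids.dmu)
    return _right_boundary(total, grids.x, frontdef.boundary_threshold)


def boundary_trace(traj: Trajectory,
                   frontdef: FrontDefinition = FrontDefinition()) -> np.ndarray:
    """Right-boundary position at every recorded time."""
    x = traj.grids.x
    thr = frontdef.boundary_threshold
    return np.array([_right_boundary(tot, x, thr) for tot in traj.total_xt])


def tumor_volume(state: TumorState, grids) -> float:
    """Total cell mass ``integral (n + H) dx`` (the 1D 'tumor volume')."""
    total = state.n + state.H(grids.dmu)
    return float(total.sum() * grids.dx)


def _front_mask(x: np.ndarray, boundary: float, depth: float) -> np.ndarray:
    return (x >= boundary - depth) & (x <= boundary + 1e-12)


def front_hypoxic_fraction(n: np.ndarray, H: np.ndarray, x: np.ndarray,
                           dx: float,
                           frontdef: FrontDefinition = FrontDefinition()
                           ) -> float:
    """Hypoxic share of the cells in the front band; NaN if empty."""
    total = n + H
    b = _right_boundary(total, x, frontdef.boundary_threshold)
    mask = _front_mask(x, b, frontdef.front_depth)
    denom = total[mask].sum() * dx
    if denom < frontdef.boundary_threshold:
        return float("nan")
    return float(H[mask].sum() * dx / denom)


def front_hypoxic_fraction_trace(traj: Trajectory,
                                 frontdef: FrontDefinition = FrontDefinition()
                                 ) -> np.ndarray:
    g = traj.grids
    return np.array([
        front_hypoxic_fraction(traj.n_xt[k], traj.H_xt[k], g.x, g.dx, frontdef)
        for k in range(len(traj.times))])


def mean_front_hypoxic_fraction(traj: Trajectory,
                                frontdef: FrontDefinition = FrontDefinition()
                                ) -> float:
    """Front hypoxic fraction averaged over all recorded outputs."""
    trace = front_hypoxic_fraction_trace(traj, frontdef)
    if np.all(np.isnan(trace)):
        return float("nan")
    return float(np.nanmean(trace))


def hitting_time(times: np.ndarray, boundary: np.ndarray,
                 x_target: float) -> float:
    """First time the right boundary reaches ``x_target``.

    Linearly interpolated between the bracketing records; NaN if the
    target is never attained.
    """
    reached = np.flatnonzero(boundary >= x_target)
    if reached.size == 0:
        return float("nan")
    k = reached[0]
    if k == 0:
        return float(times[0])
    b0, b1 = boundary[k - 1], boundary[k]
    t0, t1 = times[k - 1], times[k]
    return float(t0 + (t1 - t0) * (x_target - b0) / (b1 - b0))


# ---------------------------------------------------------------------------
# phenotype (memory) structure


def phenotype_distribution(state: TumorState, grids, region: str = "bulk",
                           frontdef: FrontDefinition = FrontDefinition(),
                           region_label: str | None = None,
                           cycle_label: str = "") -> PhenotypeDistribution | None:
    """Normalized mu-distribution of hypoxic mass in the bulk or front.

    Integrates ``h`` over the requested spatial region and normalizes to
    unit total weight.  Normoxic cells are excluded (the distribution
    describes the memory structure of the hypoxic compartment).  Returns
    ``None`` when the region holds no hypoxic mass.
    """
    if region not in ("bulk", "front"):
        raise ValueError("region must be 'bulk' or 'front'")
    if region == "front":
        b = tumor_right_boundary(state, grids, frontdef)
        mask = _front_mask(grids.x, b, frontdef.front_depth)
    else:
        mask = np.ones(grids.N, dtype=bool)
    mass = state.h[mask, :].sum(axis=0) * grids.dx
    total = mass.sum()
    if total <= 0:
        return None
    return PhenotypeDistribution(support=grids.mu, mass=mass / total,
                                 region_label=region_label or region,
                                 cycle_label=cycle_label)


def distribution_from_snapshot(h: np.ndarray, n: np.ndarray, grids,
                               region: str,
                               frontdef: FrontDefinition = FrontDefinition(),
                               cycle_label: str = ""
                               ) -> PhenotypeDistribution | None:
    """As :func:`phenotype_distribution` but from a raw ``h`` snapshot."""
    state = TumorState(t=0.0, n=n, h=h, e=np.zeros_like(n))
    return phenotype_distribution(state, grids, region, frontdef,
                                  cycle_label=cycle_label)


def strong_memory_fraction(dist: PhenotypeDistribution | None,
                           cutoff: float = 0.25) -> float:
    """Weight carried by phenotypes strictly below the cutoff (default 0.25)."""
    if dist is None:
        return float("nan")
    return float(dist.mass[dist.support < cutoff].sum())


def front_to_bulk_memory_ratio(front: PhenotypeDistribution | None,
                               bulk: PhenotypeDistribution | None,
                               cutoff: float = 0.25) -> float:
    """Ratio of strong-memory fractions, front over bulk; NaN if undefined."""
    f = strong_memory_fraction(front, cutoff)
    b = strong_memory_fraction(bulk, cutoff)
    if np.isnan(f) or np.isnan(b) or b == 0:
        return float("nan")
    return f / b


def jensen_shannon_divergence(p: PhenotypeDistribution,
                              q: PhenotypeDistribution) -> float:
    """Jensen-Shannon divergence (natural log) between two distributions.

    ``JSD = (KL(p||m) + KL(q||m)) / 2`` with ``m = (p+q)/2`` and the
    convention ``0 log 0 = 0``; bounded by ``ln 2``, symmetric, zero iff
    the distributions coincide.
    """
    if p.support.shape != q.support.shape or not np.allclose(
            p.support, q.support):
        raise ValueError("distributions must share the same support")
    pm, qm = p.mass, q.mass
    m = 0.5 * (pm + qm)

    def _kl(a: np.ndarray) -> float:
        nz = a > 0
        return float(np.sum(a[nz] * np.log(a[nz] / m[nz])))

    return 0.5 * _kl(pm) + 0.5 * _kl(qm)


def percent_change(memory_value: float, memoryless_value: float) -> float:
    """Relative change of the memory arm vs the memoryless baseline, in %.

    NaN inputs and a zero baseline propagate as NaN.
    """
    if np.isnan(memory_value) or np.isnan(memoryless_value):
        return float("nan")
    if memoryless_value == 0:
        return float("nan")
    return 100.0 * (memory_value - memoryless_value) / memoryless_value
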