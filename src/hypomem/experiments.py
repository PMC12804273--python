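"""Configuration-driven experiment runners.

Each runner is a pure function of its arguments: it assembles scenario
configurations, runs the solver, and reduces trajectories to tidy pandas
tables (one row per scenario x arm) plus a small summary dict.  The
"memory" arm uses the reference memory strength ``alpha = 0.8`` with the
requested induction/erasure timescales; the "memoryless" arm sets
``alpha = 0`` and is always included so percent-change columns are
self-contained.

Families:

* case studies — constant-oxygen verification runs against the lumped
  closed forms;
* period sweep — symmetric cyclic hypoxia, periods {5, 10, 15, 20};
* bias sweep — period-5 cycles, hypoxic fraction {0.25 ... 0.75};
* beta grid — induction x erasure timescale grid;
* memory structure — bulk/front phenotype distributions at the ends of
  the last normoxic and hypoxic phases.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import observables as obs
from .analytics import (analytic_hypoxic_decay, analytic_normoxic_logistic,
                        hypoxic_equilibrium_phenotype)
from .core import ModelParameters, OxygenProtocol
from .solver import (Grids, InitialCondition, ScenarioConfig, SolverSettings,
                     Trajectory, simulate)

__all__ = [
    "build_config",
    "load_config",
    "config_from_dict",
    "run_scenario",
    "summarize_run",
    "run_case_studies",
    "run_period_sweep",
    "run_bias_sweep",
    "run_beta_grid",
    "run_memory_structure",
    "HIT_TARGET_PERIOD",
    "HIT_TARGET_BIAS",
]

#: right-boundary hitting targets used by the sweep families
HIT_TARGET_PERIOD = 9.62
HIT_TARGET_BIAS = 9.1


# ---------------------------------------------------------------------------
# configuration plumbing


def build_config(*, memory: bool = True, beta_l: float = 2.0,
                 beta_h: float = 20.0, protocol: OxygenProtocol | None = None,
                 grids: Grids | None = None,
                 settings: SolverSettings | None = None,
                 ic: InitialCondition | None = None,
                 params: ModelParameters | None = None) -> ScenarioConfig:
    """Assemble a full scenario; ``memory=False`` zeroes alpha."""
    if params is None:
        params = ModelParameters(beta_l=beta_l, beta_h=beta_h)
    if not memory:
        params = params.memoryless()
    return ScenarioConfig(
        params=params,
        protocol=protocol if protocol is not None else OxygenProtocol(),
        grids=grids,
        settings=settings if settings is not None else SolverSettings(),
        ic=ic if ic is not None else InitialCondition(),
    )


def config_from_dict(d: dict) -> ScenarioConfig:
    """Build a scenario from a plain key-value mapping (config file schema).

    Recognized sections: ``params``, ``protocol``, ``grids``,
    ``settings``, ``ic`` — each a mapping of the corresponding dataclass
    fields; missing fields fall back to defaults.
    """
    def section(cls, key):
        sub = dict(d.get(key) or {})
        if key == "settings" and "snapshot_times" in sub:
            sub["snapshot_times"] = tuple(sub["snapshot_times"])
        return cls(**sub)

    return ScenarioConfig(
        params=section(ModelParameters, "params"),
        protocol=section(OxygenProtocol, "protocol"),
        grids=section(Grids, "grids") if d.get("grids") else None,
        settings=section(SolverSettings, "settings"),
        ic=section(InitialCondition, "ic"),
    )


def load_config(path: str | Path) -> ScenarioConfig:
    """Read a scenario from a YAML (or JSON, a YAML subset) file."""
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def run_scenario(config: ScenarioConfig) -> Trajectory:
    """Alias for :func:`hypomem.solver.simulate` (kept for symmetry)."""
    return simulate(config)


def summarize_run(traj: Trajectory, hit_target: float,
                  frontdef: obs.FrontDefinition = obs.FrontDefinition()
                  ) -> dict:
    """Reduce one trajectory to the scalar metrics used by all sweeps."""
    totals = traj.mass_totals()
    b = obs.boundary_trace(traj, frontdef)
    return {
        "final_volume": float(totals["n_tot"][-1] + totals["h_tot"][-1]),
        "final_boundary": float(b[-1]),
        "hitting_time": obs.hitting_time(traj.times, b, hit_target),
        "mean_front_h_fraction": obs.mean_front_hypoxic_fraction(traj, frontdef),
    }


def _arm_rows(label_cols: dict, protocol: OxygenProtocol, beta_l: float,
              beta_h: float, grids: Grids | None, hit_target: float,
              settings: SolverSettings | None = None,
              keep: dict | None = None) -> list[dict]:
    """Run memory + memoryless arms for one scenario, return table rows."""
    rows = []
    for arm, memory in (("memory", True), ("memoryless", False)):
        cfg = build_config(memory=memory, beta_l=beta_l, beta_h=beta_h,
                           protocol=protocol, grids=grids, settings=settings)
        traj = simulate(cfg)
        row = {**label_cols, "arm": arm,
               **summarize_run(traj, hit_target=hit_target)}
        rows.append(row)
        if keep is not None:
            keep[(tuple(label_cols.values()), arm)] = traj
    return rows


def _add_percent_changes(table: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    """Memory-vs-memoryless percent changes, one row per scenario."""
    out = []
    for key_vals, grp in table.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        mem = grp[grp.arm == "memory"].iloc[0]
        base = grp[grp.arm == "memoryless"].iloc[0]
        rec = dict(zip(keys, key_vals))
        for metric in ("final_volume", "hitting_time",
                       "mean_front_h_fraction"):
            rec[f"pct_change_{metric}"] = obs.percent_change(
                mem[metric], base[metric])
        out.append(rec)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# verification case studies (constant oxygen)


def run_case_studies(t_final: float = 60.0, grids: Grids | None = None,
                     depletion_fractions: tuple[float, ...] = (1e-3,),
                     c_hypoxic: float = 0.4, c_normoxic: float = 1.0) -> dict:
    """Constant-oxygen runs compared against the lumped closed forms.

    Case I (sustained hypoxia, default c = 0.4): normoxic mass must decay
    as ``N0 exp(-mu_nh t)`` with the total conserved; also reports the
    times at which the normoxic mass first falls below the requested
    fractions of ``N0``, and the mean phenotype at the end of the run
    (which should sit at the drift equilibrium ``mu*``).

    Case II (sustained normoxia, c = 1): no hypoxic cells, undegraded
    ECM, and logistic growth of the (spatially uniform) tumor density.
    The logistic comparison is made on the density scale — the lumped law
    describes the density inside the initially occupied region, where the
    initial condition carries no ECM.
    """
    report: dict = {}

    # --- Case I ---
    cfg1 = build_config(
        protocol=OxygenProtocol.constant(c_hypoxic, t_final=t_final),
        grids=grids,
        settings=SolverSettings(snapshot_times=(t_final,)))
    traj1 = simulate(cfg1)
    totals = traj1.mass_totals()
    N0 = float(totals["n_tot"][0])
    mu_nh = cfg1.params.mu_nh
    exact = analytic_hypoxic_decay(traj1.times, N0, mu_nh)
    sup_n = float(np.max(np.abs(totals["n_tot"] - exact.n_tot)))
    sup_h = float(np.max(np.abs(totals["h_tot"] - exact.h_tot)))
    conservation = float(np.max(np.abs(
        totals["n_tot"] + totals["h_tot"] - N0)))

    depletion = {}
    n_trace = totals["n_tot"]
    for frac in depletion_fractions:
        below = np.flatnonzero(n_trace < frac * N0)
        if below.size == 0:
            depletion[frac] = float("nan")
        else:
            k = below[0]
            t0, t1 = traj1.times[k - 1], traj1.times[k]
            y0, y1 = n_trace[k - 1], n_trace[k]
            depletion[frac] = float(t0 + (t1 - t0)
                                    * (frac * N0 - y0) / (y1 - y0))

    _, end_state = traj1.snapshots[-1]
    dist = obs.phenotype_distribution(end_state, traj1.grids, "bulk")
    mu_star = hypoxic_equilibrium_phenotype(c_hypoxic, cfg1.params)
    report["case1"] = {
        "N0": N0,
        "sup_error_n_tot": sup_n,
        "sup_error_h_tot": sup_h,
        "conservation_error": conservation,
        "depletion_times": depletion,
        "mean_phenotype_final": dist.mean if dist is not None else float("nan"),
        "equilibrium_phenotype": mu_star,
    }

    # --- Case II ---
    cfg2 = build_config(
        protocol=OxygenProtocol.constant(c_normoxic, t_final=t_final),
        grids=grids)
    traj2 = simulate(cfg2)
    totals2 = traj2.mass_totals()
    n0 = cfg2.ic.n0
    N0_2 = float(totals2["n_tot"][0])
    # density inside the initial tumor support (e = 0 there)
    density = totals2["n_tot"] / N0_2 * n0
    exact2 = analytic_normoxic_logistic(traj2.times, N0=n0, e_tot=0.0,
                                        lambda_n=cfg2.params.lambda_n)
    report["case2"] = {
        "N0": N0_2,
        "sup_error_n_density": float(np.max(np.abs(density - exact2.n_tot))),
        "max_abs_h_tot": float(np.max(np.abs(totals2["h_tot"]))),
        "max_ecm_change": float(np.max(np.abs(traj2.e_xt - traj2.e_xt[0]))),
        "final_boundary": float(obs.boundary_trace(traj2)[-1]),
    }
    return report


# ---------------------------------------------------------------------------
# sweep families (cyclic oxygen)


def run_period_sweep(periods: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0),
                     beta_l: float = 2.0, beta_h: float = 20.0,
                     bias: float = 0.5, t_final: float = 60.0,
                     grids: Grids | None = None,
                     hit_target: float = HIT_TARGET_PERIOD,
                     keep_trajectories: bool = False) -> dict:
    """Symmetric cyclic hypoxia across periods, memory vs memoryless.

    The "maximal memory effect" period is the argmax over periods of the
    combined effect score: the mean of |percent change in final volume|
    and |percent change in hitting time| (the latter skipped where the
    target is never reached).
    """
    keep: dict | None = {} if keep_trajectories else None
    rows = []
    for period in periods:
        proto = OxygenProtocol(period=period, bias=bias, t_final=t_final)
        rows += _arm_rows({"period": period}, proto, beta_l, beta_h, grids,
                          hit_target, keep=keep)
    table = pd.DataFrame(rows)
    effects = _add_percent_changes(table, ["period"])
    score = effects[["pct_change_final_volume", "pct_change_hitting_time"]
                    ].abs().mean(axis=1, skipna=True)
    effects = effects.assign(effect_score=score)
    best = float(effects.loc[score.idxmax(), "period"])
    result = {"table": table, "effects": effects,
              "max_effect_period": best,
              "max_effect_period_volume": float(
                  effects.loc[effects.pct_change_final_volume.abs().idxmax(),
                              "period"]),
              "hit_target": hit_target}
    if keep is not None:
        result["trajectories"] = keep
    hit = effects.pct_change_hitting_time.abs()
    if hit.notna().any():
        result["max_effect_period_hitting"] = float(
            effects.loc[hit.idxmax(), "period"])
    return result


def run_bias_sweep(biases: tuple[float, ...] = (0.25, 0.4, 0.5, 0.6, 0.75),
                   period: float = 5.0, beta_l: float = 2.0,
                   beta_h: float = 20.0, t_final: float = 60.0,
                   grids: Grids | None = None,
                   hit_target: float = HIT_TARGET_BIAS) -> dict:
    """Vary the hypoxic fraction of a period-5 cycle, memory vs memoryless."""
    rows = []
    for bias in biases:
        proto = OxygenProtocol(period=period, bias=bias, t_final=t_final)
        rows += _arm_rows({"bias": bias}, proto, beta_l, beta_h, grids,
                          hit_target)
    table = pd.DataFrame(rows)
    return {"table": table, "effects": _add_percent_changes(table, ["bias"]),
            "hit_target": hit_target}


def run_beta_grid(beta_ls: tuple[float, ...] = (2.0, 10.0),
                  beta_hs: tuple[float, ...] = (20.0, 50.0),
                  period: float = 5.0, bias: float = 0.5,
                  t_final: float = 60.0, grids: Grids | None = None,
                  hit_target: float = HIT_TARGET_PERIOD) -> dict:
    """Memory induction x erasure timescale grid (plus memoryless baseline).

    Reports, per metric, the spread attributable to each axis: the range
    across beta_l values (averaged over beta_h) and vice versa.
    """
    proto = OxygenProtocol(period=period, bias=bias, t_final=t_final)
    rows = []
    for bl in beta_ls:
        for bh in beta_hs:
            cfg = build_config(memory=True, beta_l=bl, beta_h=bh,
                               protocol=proto, grids=grids)
            rows.append({"beta_l": bl, "beta_h": bh, "arm": "memory",
                         **summarize_run(simulate(cfg), hit_target)})
    base_cfg = build_config(memory=False, protocol=proto, grids=grids)
    rows.append({"beta_l": float("nan"), "beta_h": float("nan"),
                 "arm": "memoryless",
                 **summarize_run(simulate(base_cfg), hit_target)})
    table = pd.DataFrame(rows)

    mem = table[table.arm == "memory"]
    sensitivity = {}
    for metric in ("final_volume", "hitting_time", "mean_front_h_fraction"):
        spread = lambda s: s.max() - s.min()
        across_bl = mem.groupby("beta_h")[metric].agg(spread).mean()
        across_bh = mem.groupby("beta_l")[metric].agg(spread).mean()
        sensitivity[metric] = {"range_across_beta_l": float(across_bl),
                               "range_across_beta_h": float(across_bh)}
    return {"table": table, "sensitivity": sensitivity,
            "hit_target": hit_target}


def run_memory_structure(periods: tuple[float, ...] = (5.0, 20.0),
                         beta_ls: tuple[float, ...] = (2.0, 10.0),
                         beta_h: float = 20.0, bias: float = 0.5,
                         t_final: float = 60.0, grids: Grids | None = None,
                         memory: bool = True,
                         strong_cutoff: float = 0.25) -> dict:
    """Phenotype (memory) structure at the last half-cycle boundaries.

    For every (period, beta_l) combination, takes full snapshots at the
    end of the last normoxic phase and the last hypoxic phase, and emits
    bulk/front normalized mu-distributions with strong-memory fractions,
    front-to-bulk ratios, and the Jensen-Shannon divergence between the
    front and bulk distributions.
    """
    rows = []
    distributions = {}
    for period in periods:
        for bl in beta_ls:
            snap_times = (t_final - bias * period, t_final)
            labels = ("end-normoxic", "end-hypoxic")
            proto = OxygenProtocol(period=period, bias=bias, t_final=t_final)
            cfg = build_config(memory=memory, beta_l=bl, beta_h=beta_h,
                               protocol=proto, grids=grids,
                               settings=SolverSettings(
                                   snapshot_times=snap_times))
            traj = simulate(cfg)
            for (t_snap, state), label in zip(traj.snapshots, labels):
                bulk = obs.phenotype_distribution(state, traj.grids, "bulk",
                                                  cycle_label=label)
                front = obs.phenotype_distribution(state, traj.grids, "front",
                                                   cycle_label=label)
                key = (period, bl, beta_h, label)
                distributions[key] = {"bulk": bulk, "front": front}
                smf_bulk = obs.strong_memory_fraction(bulk, strong_cutoff)
                smf_front = obs.strong_memory_fraction(front, strong_cutoff)
                jsd = (obs.jensen_shannon_divergence(front, bulk)
                       if bulk is not None and front is not None
                       else float("nan"))
                rows.append({
                    "period": period, "beta_l": bl, "beta_h": beta_h,
                    "cycle": label, "t_snapshot": t_snap,
                    "strong_memory_bulk": smf_bulk,
                    "strong_memory_front": smf_front,
                    "front_to_bulk_ratio": obs.front_to_bulk_memory_ratio(
                        front, bulk, strong_cutoff),
                    "jsd_front_bulk": jsd,
                })
    return {"table": pd.DataFrame(rows), "distributions": distributions}


# ---------------------------------------------------------------------------
# output helpers


def write_outputs(outdir: str | Path, name: str, table: pd.DataFrame | None,
                  manifest: dict) -> Path:
    """Write a sweep table (CSV) and its JSON manifest; returns the dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if table is not None:
        table.to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / f"{name}_manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2)
    return outdir


def _jsonable(obj):
    """Recursively strip non-JSON types (arrays, frames, dataclasses)."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()
                if not isinstance(v, (pd.DataFrame, Trajectory))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
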