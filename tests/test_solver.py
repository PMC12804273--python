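"""Discretization and time stepping: conservation, stability, oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hypomem.core import ModelParameters, OxygenProtocol
from hypomem.solver import (Grids, InitialCondition, ScenarioConfig,
                            SolverSettings, TumorState, cfl_timestep,
                            initialize_state, max_trait_speed,
                            phenotype_advection_update, simulate,
                            spatial_flux_update, step)


def random_state(grids: Grids, rng, h_scale: float = 0.3) -> TumorState:
    n = rng.uniform(0.0, 0.3, grids.N)
    e = rng.uniform(0.0, 0.3, grids.N)
    h = rng.uniform(0.0, h_scale, (grids.N, grids.M))
    return TumorState(t=0.0, n=n, h=h, e=e)


class TestGrids:
    def test_default_mesh_spacing(self, default_grids):
        assert default_grids.dx == pytest.approx(0.05)
        assert default_grids.dmu == pytest.approx(0.01)
        assert default_grids.injection_index == 50
        assert default_grids.mu[default_grids.injection_index] == 0.5

    def test_mesh_without_injection_node_rejected(self):
        with pytest.raises(ValueError):
            Grids(M=100)  # dmu = 1/99 has no node at 0.5

    def test_refinement_keeps_injection_node(self, default_grids):
        fine = default_grids.refined()
        assert fine.dx == pytest.approx(default_grids.dx / 2)
        assert fine.mu[fine.injection_index] == 0.5


class TestInitialState:
    def test_step_profiles(self, default_grids, ic):
        s = initialize_state(default_grids, ic)
        x = default_grids.x
        assert s.n[np.argmin(np.abs(x - 5.0))] == 0.5
        assert s.n[np.argmin(np.abs(x - 2.0))] == 0.0
        assert s.e[np.argmin(np.abs(x - 2.0))] == 0.5
        assert s.e[np.argmin(np.abs(x - 5.0))] == 0.0
        assert np.all(s.h == 0.0)

    def test_initial_mass_close_to_continuum(self, default_grids, ic):
        # rectangle-rule mass of the step is n0 (b - a) + n0 dx -> 1 as dx -> 0
        s = initialize_state(default_grids, ic)
        mass = s.n.sum() * default_grids.dx
        assert mass == pytest.approx(1.0, abs=2 * ic.n0 * default_grids.dx)
        assert mass == pytest.approx(
            ic.n0 * (ic.b - ic.a) + ic.n0 * default_grids.dx)

    def test_support_edge(self, default_grids, ic):
        s = initialize_state(default_grids, ic)
        rightmost = default_grids.x[np.flatnonzero(s.n > 0)[-1]]
        assert rightmost == pytest.approx(6.0)

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            InitialCondition(a=6.0, b=4.0)


class TestCflTimestep:
    def test_diffusion_bound(self, default_grids):
        # alpha = 0 drops the advection bound; small delta leaves diffusion
        p = ModelParameters(alpha=0.0, delta=1.0)
        dt = cfl_timestep(default_grids, p, OxygenProtocol(),
                          SolverSettings(cfl_safety=1.0))
        assert dt == pytest.approx(0.05 ** 2 / (2 * 0.01))  # 0.125

    def test_advection_bound(self, default_grids, params):
        # worst speed |v(mu=1, c=0.4)| = (0.8*0.6 + 0.5) / 2 = 0.49
        proto = OxygenProtocol(c2=0.4)
        assert max_trait_speed(params, proto) == pytest.approx(0.49)
        dt = cfl_timestep(default_grids, params, proto,
                          SolverSettings(cfl_safety=1.0))
        assert dt == pytest.approx(0.01 / 0.49)

    def test_memoryless_is_decay_limited(self, default_grids):
        # with alpha = 0 the advection bound vanishes; the ECM decay
        # positivity bound 1/delta is then the binding one
        p = ModelParameters(alpha=0.0)
        dt = cfl_timestep(default_grids, p, OxygenProtocol())
        assert dt == pytest.approx(0.9 / 15.0)


class TestSpatialFlux:
    def test_uniform_fields_are_stationary(self, coarse_grids, params):
        s = TumorState(0.0, n=np.full(coarse_grids.N, 0.1),
                       h=np.full((coarse_grids.N, coarse_grids.M), 0.2),
                       e=np.full(coarse_grids.N, 0.3))
        upd = spatial_flux_update(s, params, coarse_grids)
        assert np.allclose(upd, 0.0, atol=1e-14)

    def test_conservative_with_noflux_ends(self, coarse_grids, params, rng):
        s = random_state(coarse_grids, rng)
        upd = spatial_flux_update(s, params, coarse_grids)
        per_mu = upd.sum(axis=0) * coarse_grids.dx
        assert np.allclose(per_mu, 0.0, atol=1e-13)

    def test_matches_dense_laplacian_for_dilute_spike(self, coarse_grids):
        """At vanishing volume fraction the flux reduces to D_h Laplacian."""
        p = ModelParameters(xi_h=0.0)
        N, M = coarse_grids.N, coarse_grids.M
        h = np.zeros((N, M))
        h[N // 2, :] = 1e-8  # dilute: 1 - n - H - e = 1 to O(1e-8)
        s = TumorState(0.0, n=np.zeros(N), h=h, e=np.zeros(N))
        upd = spatial_flux_update(s, p, coarse_grids)

        lap = np.zeros((N, N))
        for i in range(1, N - 1):
            lap[i, i - 1: i + 2] = [1.0, -2.0, 1.0]
        lap[0, :2] = [-1.0, 1.0]          # no-flux ends
        lap[-1, -2:] = [1.0, -1.0]
        oracle = p.D_h * lap @ h / coarse_grids.dx ** 2
        assert np.allclose(upd, oracle, rtol=1e-6, atol=1e-20)


class TestPhenotypeAdvection:
    def test_zero_field(self, coarse_grids, params):
        s = TumorState(0.0, np.zeros(coarse_grids.N),
                       np.zeros((coarse_grids.N, coarse_grids.M)),
                       np.zeros(coarse_grids.N))
        upd = phenotype_advection_update(s, 0.4, params, coarse_grids)
        assert np.all(upd == 0.0)

    def test_preserves_per_x_mass(self, coarse_grids, params, rng):
        s = random_state(coarse_grids, rng)
        for c in (0.4, 1.0):
            upd = phenotype_advection_update(s, c, params, coarse_grids)
            assert np.allclose(upd.sum(axis=1) * coarse_grids.dmu, 0.0,
                               atol=1e-13)

    def test_spike_drifts_along_characteristics(self, params):
        """Mean phenotype follows d mu/dt = v(mu) toward mu* = 0.02."""
        grids = Grids(N=3, M=101)
        h = np.zeros((grids.N, grids.M))
        h[:, grids.injection_index] = 1.0 / grids.dmu
        s = TumorState(0.0, np.zeros(grids.N), h, np.zeros(grids.N))
        c = 0.4
        dt = 0.5 * grids.dmu / 0.49
        t_end = 5.0 * params.beta_l  # ~5 relaxation times

        sol = solve_ivp(
            lambda t, mu: -(params.alpha * (1 - c) + mu - params.mu_hn0)
            / params.beta_l,
            (0.0, t_end), [0.5], dense_output=True, rtol=1e-10, atol=1e-12)

        t = 0.0
        while t < t_end - 1e-12:
            s.h = s.h + dt * phenotype_advection_update(s, c, params, grids)
            t += dt
        mass = s.h[0] * grids.dmu
        mean_mu = float((grids.mu * mass).sum() / mass.sum())
        assert mean_mu == pytest.approx(float(sol.sol(t_end)[0]), abs=0.02)
        assert mean_mu == pytest.approx(0.02, abs=0.03)


class TestStep:
    def test_mass_conserved_between_thresholds(self, coarse_grids, rng):
        """c_N < c < c_H: total n + H unchanged by one step, to 1e-12."""
        params = ModelParameters()
        proto = OxygenProtocol.constant(0.4)
        s = random_state(coarse_grids, rng, h_scale=0.1)
        dt = cfl_timestep(coarse_grids, params, proto)
        dx, dmu = coarse_grids.dx, coarse_grids.dmu
        before = s.n.sum() * dx + s.h.sum() * dx * dmu
        s2 = step(s, proto, params, coarse_grids, dt)
        after = s2.n.sum() * dx + s2.h.sum() * dx * dmu
        assert after == pytest.approx(before, abs=1e-12)

    def test_ecm_untouched_without_hypoxic_cells(self, coarse_grids, params):
        proto = OxygenProtocol.constant(1.0)
        s = initialize_state(coarse_grids)
        s2 = step(s, proto, params, coarse_grids, 0.01)
        assert np.array_equal(s2.e, s.e)

    def test_zero_state_is_fixed_point(self, coarse_grids, params):
        z = TumorState(0.0, np.zeros(coarse_grids.N),
                       np.zeros((coarse_grids.N, coarse_grids.M)),
                       np.zeros(coarse_grids.N))
        s2 = step(z, OxygenProtocol(), params, coarse_grids, 0.01)
        assert np.all(s2.n == 0) and np.all(s2.h == 0) and np.all(s2.e == 0)

    def test_nan_state_aborts(self, coarse_grids, params):
        s = initialize_state(coarse_grids)
        s.n[3] = np.nan
        with pytest.raises(FloatingPointError):
            step(s, OxygenProtocol(), params, coarse_grids, 0.01)

    def test_gross_negativity_aborts(self, coarse_grids, params):
        s = initialize_state(coarse_grids)
        s.n[3] = -1e-6
        with pytest.raises(FloatingPointError):
            step(s, OxygenProtocol.constant(0.4), params, coarse_grids, 0.01)


class TestSimulate:
    def test_zero_horizon_returns_initial_state_only(self, coarse_grids):
        cfg = ScenarioConfig(protocol=OxygenProtocol(t_final=0.0),
                             grids=coarse_grids)
        traj = simulate(cfg)
        assert len(traj.times) == 1 and traj.times[0] == 0.0
        assert traj.final_state.t == 0.0

    def test_bitwise_determinism(self, coarse_grids):
        cfg = ScenarioConfig(protocol=OxygenProtocol(period=5.0, t_final=7.0),
                             grids=coarse_grids)
        t1, t2 = simulate(cfg), simulate(cfg)
        assert np.array_equal(t1.n_xt, t2.n_xt)
        assert np.array_equal(t1.H_xt, t2.H_xt)
        assert np.array_equal(t1.final_state.h, t2.final_state.h)

    def test_memoryless_mass_never_leaves_injection_node(self, coarse_grids):
        cfg = ScenarioConfig(params=ModelParameters(alpha=0.0),
                             protocol=OxygenProtocol(period=5.0, t_final=10.0),
                             grids=coarse_grids)
        traj = simulate(cfg)
        h = traj.final_state.h
        off = np.delete(h, coarse_grids.injection_index, axis=1)
        assert np.all(off == 0.0)
        assert h[:, coarse_grids.injection_index].max() > 0.0

    def test_positivity_and_ecm_monotonicity(self, coarse_grids):
        cfg = ScenarioConfig(protocol=OxygenProtocol(period=5.0, t_final=15.0),
                             grids=coarse_grids)
        traj = simulate(cfg)
        assert traj.n_xt.min() >= 0.0
        assert traj.H_xt.min() >= 0.0
        assert traj.final_state.h.min() >= 0.0
        assert np.all(np.diff(traj.e_xt, axis=0) <= 1e-15)

    def test_case1_totals_follow_exponential_decay(self, coarse_grids):
        cfg = ScenarioConfig(protocol=OxygenProtocol.constant(0.4, t_final=10.0),
                             grids=coarse_grids)
        traj = simulate(cfg)
        totals = traj.mass_totals()
        N0 = totals["n_tot"][0]
        exact = N0 * np.exp(-0.5 * traj.times)
        assert np.max(np.abs(totals["n_tot"] - exact)) < 5e-3
        assert np.max(np.abs(totals["n_tot"] + totals["h_tot"] - N0)) < 1e-10

    def test_case2_has_no_hypoxic_cells(self, coarse_grids):
        cfg = ScenarioConfig(protocol=OxygenProtocol.constant(1.0, t_final=10.0),
                             grids=coarse_grids)
        traj = simulate(cfg)
        assert np.max(np.abs(traj.H_xt)) == 0.0
        assert np.array_equal(traj.e_xt[-1], traj.e_xt[0])

    def test_snapshots_taken_at_requested_times(self, coarse_grids):
        cfg = ScenarioConfig(
            protocol=OxygenProtocol(period=5.0, t_final=5.0),
            grids=coarse_grids,
            settings=SolverSettings(snapshot_times=(2.5, 5.0)))
        traj = simulate(cfg)
        assert len(traj.snapshots) == 2
        for t_req, (t_snap, state) in zip((2.5, 5.0), traj.snapshots):
            assert t_snap == pytest.approx(t_req, abs=traj.dt + 1e-12)
            assert state.h.shape == (coarse_grids.N, coarse_grids.M)
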