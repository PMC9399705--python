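import numpy as np
import pytest

from hesdyn import (
    LatticeSpec,
    ModelParams,
    SimConfig,
    build_lattice,
    fixed_point,
    hill_auto,
    hill_li,
    mean_neighbour_protein,
    simulate,
)


class TestHillFunctions:
    def test_auto_boundary_values(self, params):
        assert hill_auto(0.0, params) == pytest.approx(1.0)
        assert hill_auto(params.p0_auto, params) == pytest.approx(0.5)
        assert hill_auto(1e12, params) == pytest.approx(0.0, abs=1e-12)

    def test_li_boundary_values(self, params):
        assert hill_li(0.0, params) == pytest.approx(1.0)
        assert hill_li(params.p0_li, params) == pytest.approx(0.5)

    def test_li_uncoupled_is_identity(self, params):
        p = params.uncoupled()
        assert np.all(hill_li(np.array([0.0, 1e4, 1e8]), p) == 1.0)

    def test_monotone_decreasing(self, params):
        grid = np.linspace(0, 1e5, 200)
        assert np.all(np.diff(hill_auto(grid, params)) < 0)
        assert np.all(np.diff(hill_li(grid, params)) < 0)

    def test_zero_li_threshold_rejected_when_coupled(self):
        with pytest.raises(ValueError):
            ModelParams(p0_li=0.0, coupling_enabled=True)


class TestNeighbourAverage:
    def test_identical_neighbours_average_to_value(self, column26_map):
        p = np.zeros(26)
        p[[9, 11]] = 1000.0  # both proximal neighbours of cell 10
        p[[8, 12]] = 1000.0  # both distal
        got = mean_neighbour_protein(p, column26_map, 10, 1.0, norm="count")
        assert got == pytest.approx(1000.0)

    def test_weighted_average_with_distal(self):
        # one proximal at 1000, one distal at 2000, eps 1.5 -> plain
        # weighted mean over the two realised neighbours
        nmap = build_lattice(LatticeSpec(3, 1))
        p = np.array([0.0, 1000.0, 2000.0])
        got = mean_neighbour_protein(p, nmap, 0, 1.5, norm="count")
        assert got == pytest.approx((1000.0 + 1.5 * 2000.0) / 2)

    def test_capacity_norm_dilutes(self):
        nmap = build_lattice(LatticeSpec(3, 1))
        p = np.array([0.0, 1000.0, 2000.0])
        got = mean_neighbour_protein(p, nmap, 0, 1.5)
        assert got == pytest.approx((1000.0 + 1.5 * 2000.0) / 10)

    def test_all_zero_neighbours(self, column26_map):
        assert mean_neighbour_protein(np.zeros(26), column26_map, 5, 1.5) == 0.0

    def test_isolated_cell_returns_zero(self):
        nmap = build_lattice(LatticeSpec(1, 1))
        assert mean_neighbour_protein([123.0], nmap, 0, 1.5) == 0.0


class TestFixedPoint:
    def test_balance_residuals(self, params):
        m_star, p_star = fixed_point(params)
        prod = params.alpha_m * hill_auto(p_star, params)
        assert abs(params.mu_m * m_star - prod) / prod < 1e-8
        assert abs(params.mu_p * p_star - params.alpha_p * m_star) < 1e-6

    def test_delay_free_dynamics_converge_to_fixed_point(self):
        # with no delay the single-cell steady state is attracting
        params = ModelParams(tau_auto=0.0, coupling_enabled=False)
        _, p_star = fixed_point(params)
        traj = simulate(params, LatticeSpec(1, 1),
                        SimConfig(duration_h=100.0, seed=0, stochastic=False))
        assert traj.p[-1, 0, 0] == pytest.approx(p_star, rel=1e-4)


class TestIntegration:
    def test_determinism_same_seed(self, params, column26):
        cfg = SimConfig(duration_h=30.0, seed=5)
        a = simulate(params, column26, cfg)
        b = simulate(params, column26, cfg)
        assert np.array_equal(a.p, b.p) and np.array_equal(a.m, b.m)

    def test_different_seeds_differ(self, params, column26):
        a = simulate(params, column26, SimConfig(duration_h=30.0, seed=5))
        b = simulate(params, column26, SimConfig(duration_h=30.0, seed=6))
        assert not np.array_equal(a.p, b.p)

    def test_non_negative_abundances(self, short_sim):
        assert (short_sim.p >= 0).all() and (short_sim.m >= 0).all()

    def test_times_uniform_and_increasing(self, short_sim):
        dt = np.diff(short_sim.times_min)
        assert np.all(dt > 0) and np.allclose(dt, dt[0])

    def test_deterministic_step_halving_converges(self, params, column26):
        base = SimConfig(duration_h=50.0, seed=3, stochastic=False)
        fine = SimConfig(duration_h=50.0, seed=3, stochastic=False, dt=0.5)
        a = simulate(params, column26, base, eps_ratio=1.5)
        b = simulate(params, column26, fine, eps_ratio=1.5)
        rel = np.abs(a.p[-1] - b.p[-1]) / (np.abs(b.p[-1]) + 1.0)
        assert rel.max() < 0.05

    def test_noise_variance_matches_propensities(self):
        # single Euler-Maruyama step on many independent cells: the
        # increment variance must equal dt * (sum of propensities)
        params = ModelParams(coupling_enabled=False)
        n = 4000
        cfg = SimConfig(duration_h=1.0, seed=9, record_interval=1.0)
        traj = simulate(params, LatticeSpec(n, 1), cfg)
        m0, p0 = traj.m[0, :, 0], traj.p[0, :, 0]
        prod_m = params.alpha_m * hill_auto(p0, params)
        drift_m = prod_m - params.mu_m * m0
        resid = traj.m[1, :, 0] - m0 - 1.0 * drift_m
        expected_var = np.mean(params.mu_m * m0 + prod_m)
        assert np.var(resid) == pytest.approx(expected_var, rel=0.1)

    def test_uncoupled_cells_are_independent(self):
        params = ModelParams(coupling_enabled=False)
        traj = simulate(params, LatticeSpec(10, 1),
                        SimConfig(duration_h=100.0, seed=2))
        # mRNA increments are noise-dominated and serially uncorrelated,
        # so ~6000 samples give a tight null band on the correlation
        x = np.diff(traj.m.reshape(len(traj.times_min), -1), axis=0)
        c = np.corrcoef(x.T)
        off = c[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_two_cell_anti_phase_states(self):
        # two coupled cells settle into persistent high/low contrast
        params = ModelParams(p0_li=4500.0, tau_li=0.0)
        traj = simulate(params, LatticeSpec(2, 1),
                        SimConfig(duration_h=150.0, seed=1, stochastic=False),
                        coupling_norm="count")
        final = np.sort(traj.p[-1].ravel())
        assert final[1] / max(final[0], 1.0) > 3.0

    def test_record_interval_must_divide(self):
        with pytest.raises(ValueError):
            SimConfig(dt=1.0, record_interval=2.5)

    def test_window_restricts_burn_in(self, short_sim):
        w = short_sim.window(20.0)
        assert w.times_h[0] == pytest.approx(short_sim.duration_h - 20.0)
        assert w.times_h[-1] == pytest.approx(short_sim.duration_h)
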