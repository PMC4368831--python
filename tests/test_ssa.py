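"""Exact SSA: reproducibility, Poisson/mean-field laws, histograms, exit times."""

import numpy as np
import pytest

import cyclescape as cs


def bd_analytic_S(x, c=1.0, k=1.0):
    return x * np.log(k * x / c) - x + c / k


class TestSimulate:
    def test_absorbing_when_all_rates_vanish(self):
        # death-only system started at zero count: no channel can fire
        net = cs.birth_death_network(0.0, 1.0, 10.0)
        traj = cs.simulate(net, [0], 10.0, seed=1)
        assert traj.absorbed
        assert len(traj.event_times) == 1

    def test_bitwise_reproducible(self, baseline):
        net = cs.build_network(baseline, 50.0)
        s0 = np.array([25.0, 0.0, 13.0])
        a = cs.simulate(net, s0, 20.0, seed=42)
        b = cs.simulate(net, s0, 20.0, seed=42)
        assert np.array_equal(a.event_times, b.event_times)
        assert np.array_equal(a.states, b.states)
        c = cs.simulate(net, s0, 20.0, seed=43)
        assert not np.array_equal(a.event_times, c.event_times)

    def test_consecutive_states_differ_by_one_channel(self, baseline):
        net = cs.build_network(baseline, 50.0)
        traj = cs.simulate(net, [25, 0, 13], 5.0, seed=3)
        nus = {tuple(nu) for nu in net.nu_matrix}
        jumps = np.diff(traj.states, axis=0)
        for j in jumps:
            assert tuple(j.astype(int)) in nus

    def test_birth_only_event_count_is_poisson(self):
        # birth rate c·V = 1, t_end = 10 -> mean 10 events
        net = cs.birth_death_network(0.1, 1e-300, 10.0)
        counts = [
            len(cs.simulate(net, [0], 10.0, seed=s).event_times) - 1 for s in range(200)
        ]
        mean = np.mean(counts)
        assert abs(mean - 10.0) < 3.0 * np.sqrt(10.0 / 200)

    def test_mean_field_deviation_scales_inverse_sqrt_volume(self):
        # LLN on the 1-D relaxation X(0)=2V -> mean V: sup-dev ~ V^(-1/2)
        t_grid = np.linspace(0.0, 5.0, 40)
        ref = 1.0 + np.exp(-t_grid)  # ODE: dx/dt = 1 - x from x(0)=2
        devs = {}
        for V in (200.0, 800.0):
            net = cs.birth_death_network(1.0, 1.0, V)
            sups = [
                np.max(np.abs(
                    cs.trajectory_at_times(cs.simulate(net, [2 * int(V)], 5.0, seed=500 + s), t_grid)[:, 0] / V
                    - ref
                ))
                for s in range(30)
            ]
            devs[V] = np.mean(sups)
        ratio = devs[200.0] / devs[800.0]
        assert 1.4 < ratio < 2.9  # ideal 2.0 for a factor-4 volume range

    def test_yeast_mean_field_deviation_decreases_with_volume(self, baseline):
        # relaxation orbit of the full network; attractor-boundary
        # sensitivity keeps this qualitative (monotone decrease only)
        t_grid = np.linspace(0.0, 15.0, 50)
        start = np.array([3.0, 3.0, 3.0])
        ref = cs.integrate(baseline, start, 15.0, n_samples=50).states
        devs = {}
        for V in (200.0, 800.0):
            net = cs.build_network(baseline, V)
            s0 = np.round(start * V)
            sups = [
                np.max(np.abs(cs.trajectory_at_times(cs.simulate(net, s0, 15.0, seed=1000 + s), t_grid) / V - ref))
                for s in range(20)
            ]
            devs[V] = np.mean(sups)
        assert devs[800.0] < devs[200.0]


class TestStationaryHistogram:
    def test_1d_birth_death_mode_near_poisson_mean(self):
        V = 40.0
        net = cs.birth_death_network(1.0, 1.0, V)  # Poisson mean = V
        edges = [np.linspace(0, 3, 61), np.array([0.0, 1.0]), np.array([0.0, 1.0])]
        hist = cs.stationary_histogram(net, [int(V)], 2000.0, bins=edges, seed=5)
        centers = 0.5 * (edges[0][1:] + edges[0][:-1])
        mode = centers[np.argmax(hist.counts[:, 0, 0])]
        assert abs(mode - 1.0) < 0.1

    def test_total_weight_conserves_time(self):
        net = cs.birth_death_network(1.0, 1.0, 40.0)
        edges = [np.linspace(0, 5, 26), np.array([0.0, 1.0]), np.array([0.0, 1.0])]
        hist = cs.stationary_histogram(net, [40], 500.0, bins=edges, seed=6)
        assert hist.total_weight == pytest.approx(500.0, rel=1e-6)

    def test_neg_log_p_matches_scaled_quasipotential(self):
        # -ln P̂ ≈ V·S(x) + const for the 1-D birth-death system
        V = 60.0
        net = cs.birth_death_network(1.0, 1.0, V)
        edges = [np.linspace(0.4, 1.8, 29), np.array([0.0, 1.0]), np.array([0.0, 1.0])]
        hist = cs.stationary_histogram(net, [int(V)], 30000.0, bins=edges, seed=7)
        grid = cs.finite_volume_landscape(hist)
        xs = grid.axes[0]
        ref = V * bd_analytic_S(xs)
        good = np.isfinite(grid.values)
        resid = grid.values[good] - ref[good]
        resid -= resid.mean()  # additive constant is arbitrary
        assert np.std(resid) < 0.35

    def test_uniform_histogram_gives_flat_landscape(self):
        edges = (np.linspace(0, 1, 5), np.linspace(0, 1, 5), np.array([0.0, 1.0]))
        counts = np.ones((4, 4, 1))
        hist = cs.OccupancyHistogram(counts, edges, 16.0, 10.0, 0)
        grid = cs.finite_volume_landscape(hist)
        assert np.allclose(grid.values, np.log(16.0))

    def test_single_bin_histogram(self):
        edges = (np.linspace(0, 1, 5), np.linspace(0, 1, 5), np.array([0.0, 1.0]))
        counts = np.zeros((4, 4, 1))
        counts[2, 1, 0] = 7.0
        grid = cs.finite_volume_landscape(cs.OccupancyHistogram(counts, edges, 7.0, 1.0, 0))
        assert grid.values[2, 1] == pytest.approx(0.0)
        assert np.isnan(grid.values[0, 0])

    def test_empty_histogram_raises(self):
        net = cs.birth_death_network(1e-300, 1.0, 10.0)
        with pytest.raises(RuntimeError):
            cs.stationary_histogram(
                net, [0], 1.0, bins=[np.array([5.0, 6.0]), np.array([0, 1.0]), np.array([0, 1.0])],
                seed=1,
            )


class TestExitTimes:
    def test_zero_when_predicate_true_at_start(self):
        net = cs.birth_death_network(1.0, 1.0, 20.0)
        res = cs.mean_exit_time(
            net, {"start": [30], "species": 0, "threshold": 25, "direction": "up"},
            n_reps=10, seed=2,
        )
        assert np.all(res.times == 0.0)

    def test_censoring_reported(self):
        net = cs.birth_death_network(1.0, 1.0, 30.0)
        res = cs.mean_exit_time(
            net, {"start": [30], "species": 0, "threshold": 80, "direction": "up"},
            n_reps=5, seed=3, t_cap=1.0,
        )
        assert res.n_censored == 5

    def test_ci_shrinks_with_replicates(self):
        net = cs.birth_death_network(1.0, 1.0, 25.0)
        basin = {"start": [25], "species": 0, "threshold": 38, "direction": "up"}
        w = {}
        for n in (60, 240):
            res = cs.mean_exit_time(net, basin, n_reps=n, seed=4)
            w[n] = res.ci[1] - res.ci[0]
        assert w[240] < w[60]  # CLT: expect ~1/2 for 4x replicates
        assert w[240] / w[60] < 0.8

    def test_volume_scaling_slope_matches_analytic_barrier(self, bd_network_factory):
        # τ ≍ C·V^{-1/2}·exp(V·ΔS) for threshold crossing at x_e
        x_e = 1.5
        dS = bd_analytic_S(x_e)
        fit = cs.exit_time_volume_scaling(
            bd_network_factory,
            volumes=(20, 30, 40, 50),
            basin_for_volume=lambda V: {
                "start": [int(V)], "species": 0,
                "threshold": int(round(x_e * V)), "direction": "up",
            },
            n_reps=100,
            seed=10,
        )
        assert fit["r2"] >= 0.95
        assert fit["ci"][0] <= dS <= fit["ci"][1]


class TestBurnIn:
    def test_burn_in_advances_state_and_conserves_remaining_time(self):
        V = 40.0
        net = cs.birth_death_network(1.0, 1.0, V)
        edges = [np.linspace(0, 3, 31), np.array([0.0, 1.0]), np.array([0.0, 1.0])]
        # start far from the Poisson mean; after burn-in the mode is near it
        hist = cs.stationary_histogram(net, [100], 800.0, bins=edges, seed=9,
                                       burn_in=100.0)
        assert hist.total_weight == pytest.approx(800.0, rel=1e-6)
        centers = 0.5 * (edges[0][1:] + edges[0][:-1])
        mode = centers[np.argmax(hist.counts[:, 0, 0])]
        assert abs(mode - 1.0) < 0.15
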