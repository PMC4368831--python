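"""Deterministic model: drift, Jacobian, fixed points, bifurcation, cycles."""

import numpy as np
import pytest

import cyclescape as cs
from cyclescape.model import _structured_starts  # noqa: F401  (import check)


def z_subsystem_root(params, x_coupling=0.0, branch="high"):
    """Closed-form root of the z balance ks·z²/(j3²+z²) = (k3+ki·x)·z."""
    c = params.k3 + params.ki * x_coupling
    disc = params.ks**2 - 4 * c**2 * params.j3**2
    assert disc > 0
    sgn = 1.0 if branch == "high" else -1.0
    return (params.ks + sgn * np.sqrt(disc)) / (2 * c)


class TestDrift:
    def test_origin_drift_is_basal_production(self, baseline):
        assert np.allclose(cs.drift(baseline, [0, 0, 0]), [baseline.a0, 0, 0])

    def test_hand_evaluated_point(self, baseline):
        # x-component at (0.5, 0, 0.3): 0.25/0.5 - 0.2*0.5 - 0 + 0.001
        b = cs.drift(baseline, [0.5, 0.0, 0.3])
        assert b[0] == pytest.approx(0.401, abs=1e-12)

    def test_z_axis_equilibrium_when_a0_zero(self, baseline):
        p = baseline.with_updates(a0=1e-300)  # effectively zero basal input
        z = z_subsystem_root(p)
        assert np.allclose(cs.drift(p, [0, 0, z]), 0.0, atol=1e-12)

    def test_negative_state_rejected(self, baseline):
        with pytest.raises(ValueError):
            cs.drift(baseline, [-0.1, 0.0, 0.0])


class TestJacobian:
    def test_origin_diagonal_is_minus_degradation(self, baseline):
        J = cs.jacobian(baseline, [0, 0, 0])
        assert J[0, 0] == pytest.approx(-baseline.k1)
        assert J[1, 1] == pytest.approx(-baseline.k2)
        assert J[2, 2] == pytest.approx(-baseline.k3)

    def test_y_diagonal_at_g1_state_dominated_by_z(self, baseline, p1):
        # at the G1 state the y-equation's linearization is ≈ -(k2 + z_max)
        J = cs.jacobian(baseline, p1.location)
        z = p1.location[2]
        # up to the tiny Hill slope at y* ~ 1e-6
        assert J[1, 1] == pytest.approx(-(baseline.k2 + z), abs=1e-4)

    @pytest.mark.parametrize("seed", [0])
    def test_matches_central_differences(self, baseline, seed):
        rng = np.random.default_rng(seed)
        for s in rng.uniform(0.05, 5.0, size=(10, 3)):
            J = cs.jacobian(baseline, s)
            h = 1e-6
            for k in range(3):
                e = np.zeros(3)
                e[k] = h
                col = (cs.drift(baseline, s + e) - cs.drift(baseline, s - e)) / (2 * h)
                assert np.allclose(J[:, k], col, rtol=1e-6, atol=1e-8)


class TestFixedPoints:
    def test_baseline_has_stable_g1_at_coupled_quadratic_root(self, p1, baseline):
        x_star = p1.location[0]
        assert p1.is_stable
        assert p1.location[2] == pytest.approx(
            z_subsystem_root(baseline, x_coupling=x_star), abs=1e-6
        )

    def test_all_records_are_roots_with_consistent_stability(self, baseline_fps, baseline):
        assert baseline_fps
        for fp in baseline_fps:
            assert np.linalg.norm(cs.drift(baseline, fp.location)) < 1e-9
            re = fp.eigenvalues.real
            expected = (
                "stable" if np.all(re < 0) else "unstable" if np.all(re > 0) else "saddle"
            )
            assert fp.stability == expected

    def test_origin_is_exact_fixed_point_without_basal_input(self, baseline):
        p = baseline.with_updates(a0=1e-300)
        fps = cs.find_fixed_points(p, n_starts=40, seed=2)
        assert any(np.allclose(fp.location, 0.0, atol=1e-9) for fp in fps)

    def test_rich_nutrient_has_no_stable_point(self):
        fps = cs.find_fixed_points(cs.preset("rich_nutrient"), seed=0)
        assert not any(fp.is_stable for fp in fps)

    def test_saddle_p2_labelled(self, baseline_fps):
        p2 = next(fp for fp in baseline_fps if fp.label == "P2")
        assert p2.stability == "saddle"


class TestTrajectories:
    def test_g1_state_is_invariant(self, baseline, p1):
        traj = cs.integrate(baseline, p1.location, 50.0)
        assert np.max(np.linalg.norm(traj.states - p1.location, axis=1)) < 1e-6

    def test_excited_orbit_passes_vertices_in_order_then_returns(self, baseline, p1):
        traj = cs.integrate(baseline, cs.excited_start(baseline), 400.0, n_samples=4000)
        t_xmax = traj.times[np.argmax(traj.states[:, 0])]
        t_ymax = traj.times[np.argmax(traj.states[:, 1])]
        z = traj.states[:, 2]
        # final z rise: last time z crosses upward through half its final value
        rise = np.where((z[:-1] < z[-1] / 2) & (z[1:] >= z[-1] / 2))[0]
        t_zrise = traj.times[rise[-1]]
        assert t_xmax < t_ymax < t_zrise
        assert np.linalg.norm(traj.final_state - p1.location) < 1e-4
        # near-passes of the S and early-M vertices
        P = cs.passage_points(baseline)
        d3 = np.linalg.norm(traj.states - P["P3"], axis=1).min()
        d4 = np.linalg.norm(traj.states - P["P4"], axis=1).min()
        assert d3 < 0.1 and d4 < 0.1

    def test_nonnegativity_from_random_interior_starts(self, baseline):
        rng = np.random.default_rng(7)
        for s0 in rng.uniform(0.1, 5.0, size=(5, 3)):
            traj = cs.integrate(baseline, s0, 100.0)
            assert np.min(traj.states) >= 0.0


class TestBifurcation:
    def test_critical_a0_matches_saddle_node_of_x_subsystem(self, baseline):
        a0c = cs.locate_bifurcation_a0(baseline, (0.001, 0.01), tolerance=1e-5)
        assert a0c == pytest.approx(0.0025, rel=0.05)

    def test_nested_brackets_under_tolerance_halving(self, baseline):
        a = cs.locate_bifurcation_a0(baseline, (0.001, 0.01), tolerance=4e-4)
        b = cs.locate_bifurcation_a0(baseline, (0.001, 0.01), tolerance=2e-4)
        assert abs(a - b) <= 4e-4

    def test_unbracketed_range_raises(self, baseline):
        with pytest.raises(ValueError):
            cs.locate_bifurcation_a0(baseline, (0.0001, 0.0005))

    def test_consistency_with_fixed_point_search(self, baseline):
        a0c = cs.locate_bifurcation_a0(baseline, (0.001, 0.01), tolerance=1e-4)
        below = cs.find_fixed_points(baseline.with_updates(a0=0.9 * a0c), seed=0)
        above = cs.find_fixed_points(baseline.with_updates(a0=1.1 * a0c), seed=0)
        assert any(fp.label == "P1" for fp in below)
        assert not any(fp.label == "P1" for fp in above)


class TestLimitCycle:
    def test_rich_nutrient_cycle_and_return_consistency(self):
        cyc = cs.detect_limit_cycle(cs.preset("rich_nutrient"))
        assert cyc is not None
        assert cyc.period > 0
        # successive states one period apart agree
        p = cs.preset("rich_nutrient")
        traj = cs.integrate(p, cyc.samples[0], cyc.period, n_samples=50)
        assert np.linalg.norm(traj.final_state - cyc.samples[0]) < 0.02

    def test_baseline_converges_no_cycle(self, baseline):
        assert cs.detect_limit_cycle(baseline) is None

    def test_period_stable_under_tighter_integration(self):
        p = cs.preset("rich_nutrient")
        c1 = cs.detect_limit_cycle(p, rtol=1e-8)
        c2 = cs.detect_limit_cycle(p, rtol=1e-10)
        assert abs(c1.period - c2.period) < 0.01 * c1.period


class TestSensitivityScan:
    def test_structure_and_zero_perturbation(self, baseline):
        table = cs.sensitivity_scan(baseline, perturbation_fraction=0.2,
                                    parameters=("a0", "ka1"))
        assert len(table) == 4
        assert set(table["direction"]) == {"up", "down"}
        # a0 +20% (=0.0012) stays below the bifurcation: still excitable
        row = table[(table.parameter == "a0") & (table.direction == "up")].iloc[0]
        assert row.regime == "excitable"

    def test_zero_fraction_reproduces_baseline_depth(self, baseline):
        table = cs.sensitivity_scan(
            baseline, perturbation_fraction=0.0,
            well_depth_fn=lambda p: p.a0 * 1000.0,  # cheap stand-in depth functional
            parameters=("j1",),
        )
        assert np.allclose(table["delta_S"], 0.0)


def test_fixed_points_report_lists_all_records(baseline_fps):
    text = cs.fixed_points_report(baseline_fps)
    assert len(text.splitlines()) == len(baseline_fps) + 1
    assert any("P1" in line and "stable" in line for line in text.splitlines())
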