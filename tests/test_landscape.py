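"""Lattice quasi-potential grids: oracles, diagnostics, gluing, sections."""

import numpy as np
import pytest

import cyclescape as cs
from cyclescape.landscape import _fw_weights


def bd_analytic_S(x, c=1.0, k=1.0):
    return x * np.log(k * x / c) - x + c / k


@pytest.fixture(scope="module")
def Hbd():
    return cs.JumpHamiltonian.from_network(cs.birth_death_network(1.0, 1.0, 100.0))


@pytest.fixture(scope="module")
def grid_bd(Hbd):
    return cs.quasipotential_grid(Hbd, [np.linspace(0.25, 3.0, 111)], [1.0])


class TestOneDimensionalOracle:
    def test_matches_closed_form(self, grid_bd):
        xs = grid_bd.axes[0]
        ref = bd_analytic_S(xs)
        err = np.abs(grid_bd.values - ref)
        assert np.nanmax(err) < 5e-3

    def test_zero_at_attractor_and_nonnegative(self, grid_bd):
        assert np.nanmin(grid_bd.values) >= 0.0
        assert grid_bd.value_at([1.0]) == pytest.approx(0.0, abs=1e-9)


class TestHJResidual:
    def test_zero_landscape_has_zero_residual(self, baseline_H):
        axes = [np.linspace(0, 6, 11)] * 3
        grid = cs.LandscapeGrid(np.zeros((11, 11, 11)), tuple(axes))
        res = cs.hj_residual(grid, baseline_H)
        assert res["max"] == pytest.approx(0.0, abs=1e-12)

    def test_analytic_1d_converges_to_zero_under_refinement(self, Hbd):
        means = []
        for n in (51, 101, 201):
            xs = np.linspace(0.5, 2.5, n)
            grid = cs.LandscapeGrid(bd_analytic_S(xs), (xs,))
            means.append(cs.hj_residual(grid, Hbd)["mean"])
        assert means[0] > means[1] > means[2]
        assert means[-1] < 1e-3

    def test_baseline_grid_residual_decreases_21_to_41(self, grid21, grid41, baseline_H):
        r21 = cs.hj_residual(grid21, baseline_H)
        r41 = cs.hj_residual(grid41, baseline_H)
        assert r41["mean"] < r21["mean"]


class TestLyapunov:
    def test_nonincreasing_along_relaxation_trajectories(self, grid41, baseline):
        # S is a Lyapunov function of the deterministic flow; allow only
        # grid-interpolation wiggle: tol = h * median |∇S| over visited cells
        interp = grid41.interpolator()
        h = grid41.axes[0][1] - grid41.axes[0][0]
        gnorm = np.linalg.norm(grid41.gradient(), axis=-1)
        tol = h * np.nanmedian(gnorm)
        rng = np.random.default_rng(11)
        for s0 in rng.uniform(0.3, 5.5, size=(10, 3)):
            traj = cs.integrate(baseline, s0, 120.0, n_samples=800)
            vals = interp(traj.states)
            vals = vals[np.isfinite(vals)]
            increases = np.diff(vals)
            assert np.max(increases, initial=0.0) < tol


class TestForceField:
    def test_equals_drift_where_gradient_vanishes(self, baseline_H):
        s = np.array([[2.0, 0.05, 0.02]])
        F = baseline_H.dH_dp(s, np.zeros((1, 3)))
        b = baseline_H.drift(s)
        assert np.allclose(F, b, rtol=0, atol=1e-14)

    def test_extrinsic_force_is_drift_plus_gradient(self):
        Hx = cs.AdditiveNoiseHamiltonian(lambda x: -x, 3)
        axes = [np.linspace(-1, 1, 21)] * 3
        vals = np.zeros((21, 21, 21))
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        vals = np.sum(pts**2, axis=-1)  # S = |x|²  -> ∇S = 2x
        grid = cs.LandscapeGrid(vals, tuple(axes))
        F = cs.force_field(grid, Hx)
        expected = -pts + grid.gradient()
        assert np.allclose(F, expected, atol=1e-10)

    def test_canal_force_small_near_vertices_large_mid_canal(
        self, grid41, baseline_H, baseline, canal_path
    ):
        F = cs.force_field(grid41, baseline_H)
        interp_F = [
            cs.LandscapeGrid(F[..., k], grid41.axes).interpolator() for k in range(3)
        ]

        def fnorm(point):
            return np.linalg.norm([ip([point])[0] for ip in interp_F])

        P = cs.passage_points(baseline)
        # mid-canal reference points: path nodes far from both vertices
        d3 = np.linalg.norm(canal_path - P["P3"], axis=1)
        d4 = np.linalg.norm(canal_path - P["P4"], axis=1)
        mid_mask = (d3 > 1.5) & (d4 > 1.5) & (np.arange(len(canal_path)) > 20)
        mid_vals = [fnorm(q) for q in canal_path[mid_mask][::10]]
        near3 = fnorm(canal_path[np.argmin(d3)])
        near4 = fnorm(canal_path[np.argmin(d4)])
        assert max(near3, near4) < min(mid_vals)


class TestGluing:
    def test_single_attractor_identity(self, grid21):
        assert cs.glue_landscapes([grid21], [grid21.meta["attractor"]]) is grid21

    def test_symmetric_double_well_recovers_twice_potential(self):
        # U(x) = (x²−1)²/4: wells at ±1, saddle at 0; glued S should be 2U
        def U(x):
            return 0.25 * (x**2 - 1.0) ** 2

        H = cs.AdditiveNoiseHamiltonian(lambda x: -(x**3 - x), 1)
        xs = np.linspace(-1.6, 1.6, 161)
        g1 = cs.quasipotential_grid(H, [xs], [-1.0])
        g2 = cs.quasipotential_grid(H, [xs], [1.0])
        glued = cs.glue_landscapes([g1, g2], [[-1.0], [1.0]])
        ref = 2.0 * U(xs)
        assert np.nanmax(np.abs(glued.values - ref)) < 0.01
        assert np.nanmin(glued.values) == 0.0

    def test_fw_weights_two_state(self):
        V = np.array([[0.0, 3.0], [1.0, 0.0]])
        W = _fw_weights(V)
        assert np.allclose(W, [1.0, 3.0])

    def test_disconnected_graph_raises(self, grid21):
        g2 = cs.LandscapeGrid(np.full_like(grid21.values, np.nan), grid21.axes)
        with pytest.raises(ValueError):
            cs.glue_landscapes([grid21, g2], [[0.006, 0, 4.32], [3.0, 3.0, 3.0]])


class TestSections:
    def test_min_project_equals_slice_for_constant_axis(self):
        vals = np.tile(np.arange(25.0).reshape(5, 5), (4, 1, 1)).transpose(1, 2, 0)
        grid = cs.LandscapeGrid(
            vals, (np.arange(5.0), np.arange(5.0), np.arange(4.0))
        )
        proj = grid.min_project(2)
        sl = grid.slice_at(2, 1.0)
        assert np.allclose(proj.values, sl.values)

    def test_out_of_range_slice_raises(self, grid21):
        with pytest.raises(ValueError):
            grid21.slice_at(2, 7.5)

    def test_rich_nutrient_projection_is_ring_valley(self):
        # limit-cycle landscape projected on (y, z): zero-level ring encloses
        # an elevated interior with no strict interior minimum
        p = cs.preset("rich_nutrient")
        cyc = cs.detect_limit_cycle(p)
        H = cs.JumpHamiltonian.from_network(cs.build_network(p, 1.0))
        axes = [np.linspace(0, 6, 21)] * 3
        grid = cs.quasipotential_grid(H, axes, cyc.samples[::8])
        proj = grid.min_project(0)
        # interior point of the cycle's (y,z) loop is elevated
        interior = proj.value_at([1.2, 0.6])
        on_ring = min(proj.value_at(q[1:]) for q in cyc.samples[::40])
        assert on_ring == pytest.approx(0.0, abs=1e-6)
        assert interior > 0.05
        mins = cs.local_minima(proj, depth=0.02)
        from matplotlib.path import Path

        loop = Path(cyc.samples[:, 1:])
        for point, _ in mins:
            # any strict minimum must lie on the ring valley, not strictly inside it
            assert not loop.contains_point(point, radius=-0.3)

    def test_save_load_roundtrip(self, grid21, tmp_path):
        f = tmp_path / "grid.npz"
        grid21.save(f)
        back = cs.LandscapeGrid.load(f)
        assert np.allclose(back.values, grid21.values, equal_nan=True)
        assert back.meta["hamiltonian"] == "intrinsic_jump"


class TestBasinDepth:
    def test_parabolic_basin_depth(self):
        xs = np.linspace(-2, 2, 81)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        grid = cs.LandscapeGrid(X**2 + Y**2, (xs, xs))
        d = cs.basin_depth(grid, (0.0, 0.0), radius=0.5, shell_width=0.3)
        assert d == pytest.approx(0.25, abs=0.05)

    def test_flat_region_has_no_depth(self):
        xs = np.linspace(0, 1, 30)
        grid = cs.LandscapeGrid(np.ones((30, 30)), (xs, xs))
        assert cs.basin_depth(grid, (0.5, 0.5), radius=0.2) == pytest.approx(0.0)


class TestPlaneRestriction:
    def test_plane_restricted_charges_out_of_plane_holding(self, baseline_H):
        # in the z=0 plane the z births (ka2·y) must be suppressed to stay
        # in plane, so an in-plane move costs at least as much as the free
        # 3-D move in the same direction
        H2 = cs.plane_restricted(baseline_H, {2: 0.0})
        assert H2.dim == 2
        x2 = np.array([[2.0, 1.0]])
        u2 = np.array([[0.0, 1.0]])
        ell2 = H2.geometric_lagrangian(x2, u2)
        ell3 = baseline_H.geometric_lagrangian(
            np.array([[2.0, 1.0, 0.0]]), np.array([[0.0, 1.0, 0.0]])
        )
        assert np.isfinite(ell2[0])
        assert ell2[0] >= ell3[0] - 1e-12
        # zero in-plane momentum still gives H = 0 and F = in-plane drift
        assert H2.hamiltonian(x2, np.zeros((1, 2)))[0] == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(H2.dH_dp(x2, np.zeros((1, 2))), H2.drift(x2))
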