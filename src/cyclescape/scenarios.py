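"""End-to-end signal-response experiments on the cell-cycle landscape.

Named presets reproduce the model's signal responses:

* ``baseline`` — poor nutrients, excitable: stable G1 global minimum and
  a flat canal;
* ``rich_nutrient`` — a0 raised to 0.01 (past the bifurcation at
  a0 ≈ 0.0025): the stable G1 state disappears and the landscape shows a
  closed limit-cycle valley;
* ``s_checkpoint`` — ka1 lowered to 0.0001 (DNA-replication checkpoint):
  the flat canal near the S-phase vertex P3 turns into a pit that holds
  the system until the checkpoint is released;
* ``m_checkpoint`` — ka2 lowered to 0.0001: the analogous pit near P4.

Checkpoint pit basins span ~0.003–0.05 concentration units and are
invisible on uniform production grids, so scenario landscapes use graded
axes (dense near the coordinate planes and near the vertices) and the
multi-attractor Freidlin–Wentzell gluing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hamiltonians import JumpHamiltonian
from .landscape import LandscapeGrid, basin_depth, glue_landscapes, quasipotential_grid
from .model import (
    FixedPointRecord,
    classify_regime,
    detect_limit_cycle,
    find_fixed_points,
    passage_points,
)
from .network import build_network
from .params import ModelParams, PRESETS, preset
from .ssa import finite_volume_landscape, stationary_histogram

__all__ = [
    "Scenario",
    "scenario",
    "run_scenario",
    "compare_scenarios",
    "scenario_axes",
    "g1_well_depth",
]


def g1_well_depth(params: ModelParams, n_nodes: int = 30) -> float:
    """ΔS of the G1 basin: minimized geometric action from P1 to the
    Start saddle P2 under the intrinsic-noise Hamiltonian.

    The operational well depth — mean escape time scales as exp(V·ΔS).
    Intended as the ``well_depth_fn`` of ``model.sensitivity_scan``.
    Raises when the parameter set has no stable G1 state (past the
    nutrient bifurcation the well has vanished).
    """
    from .action import minimize_action
    from .hamiltonians import JumpHamiltonian as _JH

    fps = find_fixed_points(params, n_starts=80, seed=5)
    p1 = next((fp for fp in fps if fp.label == "P1"), None)
    p2 = next((fp for fp in fps if fp.label == "P2"), None)
    if p1 is None or p2 is None:
        raise RuntimeError("no stable G1 state / Start saddle at these parameters")
    H = _JH.from_network(build_network(params, 1.0))
    path = minimize_action(p1.location, p2.location, H, n_nodes=n_nodes)
    return path.action


@dataclass
class Scenario:
    name: str
    params: ModelParams
    expected_regime: str
    expected_features: tuple[str, ...] = ()


_EXPECTATIONS = {
    "baseline": ("excitable", ("stable_g1",)),
    "rich_nutrient": ("limit_cycle", ("no_stable_fixed_point",)),
    "s_checkpoint": ("excitable", ("stable_g1", "pit_near_P3")),
    "m_checkpoint": ("excitable", ("stable_g1", "pit_near_P4")),
}


def scenario(name: str, **overrides: float) -> Scenario:
    """A named preset, optionally with extra parameter overrides."""
    if name in PRESETS:
        params = preset(name).with_updates(**overrides)
        regime, features = _EXPECTATIONS[name]
    else:
        params = ModelParams(**overrides)
        regime, features = "unknown", ()
    return Scenario(name, params, regime, features)


def scenario_axes() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Graded rectilinear axes resolving axis-hugging canal structure."""
    xy = np.array(
        [0.0, 0.002, 0.004, 0.007, 0.012, 0.02, 0.035, 0.06, 0.1, 0.17, 0.28,
         0.45, 0.7, 1.0, 1.4, 1.9, 2.4, 3.0, 3.6, 4.1, 4.3, 4.5, 4.65, 4.8,
         4.9, 5.0, 5.1, 5.25, 5.5, 6.0]
    )
    z = np.array(
        [0.0, 0.002, 0.005, 0.012, 0.025, 0.05, 0.1, 0.2, 0.35, 0.6, 1.0, 1.5,
         2.0, 2.6, 3.2, 3.8, 4.1, 4.35, 4.6, 5.0, 5.5, 6.0]
    )
    return xy, xy.copy(), z


def _scenario_landscape(
    params: ModelParams,
    stable: Sequence[FixedPointRecord],
    axes,
) -> LandscapeGrid:
    H = JumpHamiltonian.from_network(build_network(params, 1.0))
    if stable:
        attractors = [fp.location for fp in stable]
        grids = [quasipotential_grid(H, axes, a) for a in attractors]
        return glue_landscapes(grids, attractors)
    cycle = detect_limit_cycle(params)
    if cycle is None:
        raise RuntimeError("no stable fixed point and no limit cycle found")
    return quasipotential_grid(H, axes, cycle.samples[::4])


def run_scenario(
    sc: Scenario | str,
    plan: str | Sequence[str] = "full",
    seed: int = 0,
    axes=None,
    pit_min_depth: float = 0.005,
    ssa_volume: float = 100.0,
    ssa_t_total: float = 8000.0,
) -> dict:
    """Run the analyses selected by ``plan`` and evaluate expectations.

    ``plan``: "fast" = fixed points + regime; "full" adds the glued
    quasi-potential landscape, its z=0 / x=0 slices and pit detection;
    include ``"ssa"`` in an explicit plan sequence for the finite-volume
    conditioned histogram.  Sub-analysis failures are recorded in
    ``report["errors"]`` and the report is still produced.
    """
    if isinstance(sc, str):
        sc = scenario(sc)
    if isinstance(plan, str):
        steps = {"fast": {"fixed_points", "regime"}}.get(
            plan, {"fixed_points", "regime", "landscape", "slices"}
        )
    else:
        steps = set(plan) | {"fixed_points", "regime"}

    report: dict = {"name": sc.name, "params": sc.params.as_dict(), "errors": {}}
    fps = find_fixed_points(sc.params, seed=seed)
    stable = [fp for fp in fps if fp.is_stable]
    report["fixed_points"] = fps
    report["stable_fixed_points"] = stable
    report["regime"] = classify_regime(sc.params)
    try:
        vertices = passage_points(sc.params)
        report["P3"], report["P4"] = vertices["P3"], vertices["P4"]
    except Exception as exc:
        report["errors"]["passage_points"] = str(exc)
        report["P3"], report["P4"] = np.array([4.95, 0, 0]), np.array([0, 4.95, 0])

    features: dict[str, bool] = {
        "stable_g1": any(fp.label == "P1" for fp in fps),
        "no_stable_fixed_point": not stable,
    }

    if "landscape" in steps:
        try:
            grid = _scenario_landscape(sc.params, stable, axes or scenario_axes())
            report["landscape"] = grid
            if "slices" in steps or True:
                sl_z0 = grid.slice_at(2, 0.0)
                sl_x0 = grid.slice_at(0, 0.0)
                report["slice_z0"], report["slice_x0"] = sl_z0, sl_x0
                d3 = basin_depth(sl_z0, (report["P3"][0], 0.0), radius=0.5)
                d4 = basin_depth(sl_x0, (report["P4"][1], 0.0), radius=0.5)
                report["pit_depth_P3"], report["pit_depth_P4"] = d3, d4
                features["pit_near_P3"] = bool(np.isfinite(d3) and d3 > pit_min_depth)
                features["pit_near_P4"] = bool(np.isfinite(d4) and d4 > pit_min_depth)
        except Exception as exc:
            report["errors"]["landscape"] = str(exc)

    if "ssa" in steps:
        try:
            net = build_network(sc.params, ssa_volume)
            p1 = next((fp for fp in fps if fp.label == "P1"), None)
            restart = None
            if p1 is not None:
                from .model import excited_start, integrate

                traj = integrate(sc.params, excited_start(sc.params), 60.0)
                past = traj.states[np.argmax(traj.states[:, 0] > 0.5)]
                restart = {
                    "restart_state": np.round(past * ssa_volume),
                    "g1_lo": [-1, -1, 2.0],
                    "g1_hi": [0.2, 0.2, np.inf],
                    "exclude_center": p1.location,
                    "exclude_radius": 0.5,
                }
                s0 = restart["restart_state"]
            else:
                s0 = np.round(np.array([1.0, 0.1, 0.1]) * ssa_volume)
            hist = stationary_histogram(
                net, s0, ssa_t_total, seed=seed, restart_rule=restart
            )
            report["fv_landscape"] = finite_volume_landscape(hist)
        except Exception as exc:
            report["errors"]["ssa"] = str(exc)

    report["features"] = features
    expected = dict.fromkeys(sc.expected_features, True)
    report["expected_features"] = {
        name: (features.get(name), features.get(name) == want)
        for name, want in expected.items()
        if name in features
    }
    report["regime_as_expected"] = (
        sc.expected_regime in ("unknown", report["regime"])
    )
    return report


def _match_points(a: Sequence[np.ndarray], b: Sequence[np.ndarray], tol: float = 0.1):
    unmatched = []
    for p in a:
        if not any(np.linalg.norm(p - q) < tol for q in b):
            unmatched.append(p)
    return unmatched


def compare_scenarios(report_a: dict, report_b: dict) -> dict:
    """Feature-level diff of two scenario reports (empty dict if identical)."""
    ga, gb = report_a.get("landscape"), report_b.get("landscape")
    if ga is not None and gb is not None:
        if any(len(x) != len(y) or not np.allclose(x, y) for x, y in zip(ga.axes, gb.axes)):
            raise ValueError("incompatible grid specifications")
    diff: dict = {}
    summary: list[str] = []
    if report_a["regime"] != report_b["regime"]:
        diff["regime"] = (report_a["regime"], report_b["regime"])
        summary.append(f"regime changed: {report_a['regime']} -> {report_b['regime']}")
        if report_b["regime"] == "limit_cycle":
            summary.append("closed valley added")
    locs_a = [fp.location for fp in report_a["stable_fixed_points"]]
    locs_b = [fp.location for fp in report_b["stable_fixed_points"]]
    removed = _match_points(locs_a, locs_b)
    added = _match_points(locs_b, locs_a)
    if removed:
        diff["stable_fixed_points_removed"] = removed
        summary.append(f"stable fixed point removed ({len(removed)})")
    if added:
        diff["stable_fixed_points_added"] = added
        summary.append(f"stable fixed point added ({len(added)})")
    fa, fb = report_a.get("features", {}), report_b.get("features", {})
    for key in ("pit_near_P3", "pit_near_P4"):
        va, vb = fa.get(key), fb.get(key)
        if va is not None and vb is not None and va != vb:
            diff.setdefault("pits_added" if vb else "pits_removed", []).append(key)
            where = "P3" if "P3" in key else "P4"
            summary.append(
                f"local minimum {'added' if vb else 'removed'} near {where}"
            )
    da, db = report_a.get("pit_depth_P3"), report_b.get("pit_depth_P3")
    if da is not None and db is not None and np.isfinite(da) and np.isfinite(db):
        if abs(db - da) > 1e-3:
            diff["pit_depth_P3_change"] = float(db - da)
    if summary:
        diff["summary"] = summary
    return diff
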