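"""Local pseudo energy landscape along the cell-cycle canal.

The global quasi-potential is flat along the canal, so it cannot show
the direction or speed of traversal.  The pseudo landscape restores this
by construction: remove the globally stable G1 state from consideration
and, along the deterministic path from the Start saddle,

* encode the driving-force strength as tangential steepness,
  T(s) = −∫₀ˢ ‖b(φ(u))‖ du (strictly decreasing — the canal becomes
  unidirectionally downhill), and
* keep the transverse landscape unchanged: at each section the local
  quasi-potential is evaluated in directions normal to the path.

The combined value near the path is T(s*) + S_⊥, with s* the arc length
of the nearest path point.  T(s) = −∫‖b‖ds is the minimal construction
satisfying the two defining properties (tangential slope ‖b‖; transverse
profile preserved); it is isolated behind ``tangential_potential`` so an
alternative (e.g. −∫‖b‖² ds) can be swapped.  This is a local object: it
does not represent a stationary distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .action import geometric_action, resample_arclength
from .hamiltonians import HamiltonianSpec
from .model import drift, excited_start, find_fixed_points, integrate
from .params import ModelParams

__all__ = ["PseudoLandscape", "build_pseudo", "canal_width_profile", "transverse_profile"]


def _frame(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit normals per path node (smooth-ish frame via projection)."""
    t = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    ref = np.tile([0.0, 0.0, 1.0], (len(t), 1))
    swap = np.abs(t @ np.array([0.0, 0.0, 1.0])) > 0.9
    ref[swap] = [0.0, 1.0, 0.0]
    n1 = ref - (np.sum(ref * t, axis=1, keepdims=True)) * t
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(t, n1)
    return n1, n2


def transverse_profile(
    H: HamiltonianSpec,
    point: np.ndarray,
    direction: np.ndarray,
    extent: float,
    n_steps: int = 24,
    clip_nonnegative: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Action along a straight ray from ``point`` in ``direction``.

    Straight transverse rays are near-optimal for narrow canal walls; the
    returned profile is an upper bound on the local quasi-potential in
    that direction.  Rays are truncated at the nonnegative-orthant
    boundary for jump Hamiltonians.
    """
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    if clip_nonnegative is None:
        clip_nonnegative = getattr(H, "kind", "") == "intrinsic_jump"
    dmax = float(extent)
    if clip_nonnegative:
        for k in range(len(point)):
            if direction[k] < -1e-12:
                dmax = min(dmax, (point[k] - 0.0) / -direction[k])
    dists = np.linspace(0.0, max(dmax, 1e-9), n_steps + 1)
    vals = np.zeros_like(dists)
    for i in range(1, len(dists)):
        seg = np.vstack([point + dists[i - 1] * direction, point + dists[i] * direction])
        vals[i] = vals[i - 1] + geometric_action(seg, H)
    return dists, vals


@dataclass
class PseudoLandscape:
    reference_path: np.ndarray  # (n, 3) arc-length resampled
    arclength: np.ndarray  # (n,)
    tangential_potential: np.ndarray  # T(s), strictly decreasing
    speed: np.ndarray  # ‖b‖ along the path = |dT/ds|
    H: HamiltonianSpec
    transverse_extent: float
    meta: dict = field(default_factory=dict)

    def value(self, points: np.ndarray) -> np.ndarray:
        """Pseudo energy T(s*) + S_⊥ at arbitrary points near the path.

        Nearest-path-node assignment (ties broken toward smaller s);
        the transverse part is the straight-ray action from that node.
        """
        points = np.atleast_2d(np.asarray(points, float))
        out = np.empty(len(points))
        for i, q in enumerate(points):
            d2 = np.sum((self.reference_path - q) ** 2, axis=1)
            j = int(np.argmin(d2))
            base = self.reference_path[j]
            offset = q - base
            r = np.linalg.norm(offset)
            if r < 1e-12:
                out[i] = self.tangential_potential[j]
                continue
            seg = np.vstack([base, q])
            out[i] = self.tangential_potential[j] + geometric_action(seg, self.H)
        return out


def reference_cycle_path(
    params: ModelParams, n_nodes: int = 300, t_end: float = 400.0
) -> np.ndarray:
    """Deterministic canal path from just past P2 to the G1 state."""
    traj = integrate(params, excited_start(params), t_end, n_samples=6000)
    states = traj.states
    fps = find_fixed_points(params, n_starts=80, seed=1)
    p1 = next((fp for fp in fps if fp.label == "P1"), None)
    if p1 is not None:
        d = np.linalg.norm(states - p1.location, axis=1)
        arrived = np.where(d < 0.05)[0]
        if arrived.size:
            states = states[: max(int(arrived[0]), 2) + 1]
    return resample_arclength(states, n_nodes)


def build_pseudo(
    params: ModelParams,
    H: HamiltonianSpec,
    path_resolution: int = 300,
    transverse_extent: float = 1.0,
) -> PseudoLandscape:
    """Construct the pseudo landscape for the canal of ``params``."""
    path = reference_cycle_path(params, n_nodes=path_resolution)
    seg = np.diff(path, axis=0)
    ds = np.linalg.norm(seg, axis=1)
    if np.any(ds <= 0):
        raise RuntimeError("reference path degenerated (repeated nodes)")
    s = np.concatenate([[0.0], np.cumsum(ds)])
    speed = np.linalg.norm(drift(params, path), axis=1)
    # T(s) = -∫ ||b|| ds, trapezoid rule; strictly decreasing since ||b||>0
    T = -np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * ds)])
    return PseudoLandscape(
        path, s, T, speed, H, transverse_extent,
        meta={"params": params.as_dict(), "construction": "T(s) = -int ||b|| ds"},
    )


def canal_width_profile(
    H: HamiltonianSpec,
    path: np.ndarray,
    energy_offset: float,
    transverse_extent: float = 1.5,
    n_sections: int = 40,
    n_steps: int = 30,
    clip_nonnegative: bool | None = None,
) -> dict[str, np.ndarray]:
    """Transverse half-width of the canal at a fixed energy offset.

    At ``n_sections`` points along the path, march along the four normal
    rays (±n1, ±n2) until the local quasi-potential rises by
    ``energy_offset`` above the canal floor; the width at each section is
    the mean of the per-ray crossing distances.  Rays that never reach
    the offset within ``transverse_extent`` report the extent and are
    flagged.
    """
    path = resample_arclength(np.asarray(path, float), n_sections)
    seg = np.gradient(path, axis=0)
    n1, n2 = _frame(seg)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(path, axis=0), axis=1))])
    widths = np.zeros(n_sections)
    truncated = np.zeros(n_sections, dtype=bool)
    for i in range(n_sections):
        per_ray = []
        for ray in (n1[i], -n1[i], n2[i], -n2[i]):
            dists, vals = transverse_profile(
                H, path[i], ray, transverse_extent, n_steps, clip_nonnegative
            )
            if dists[-1] < 0.25 * transverse_extent:
                continue  # ray blocked by the orthant boundary; not a fluctuation direction
            above = np.where(vals >= energy_offset)[0]
            if above.size:
                j = above[0]
                # linear interpolation to the crossing
                if j == 0:
                    per_ray.append(0.0)
                else:
                    f = (energy_offset - vals[j - 1]) / (vals[j] - vals[j - 1])
                    per_ray.append(dists[j - 1] + f * (dists[j] - dists[j - 1]))
            else:
                per_ray.append(dists[-1])
                truncated[i] = True
        widths[i] = float(np.mean(per_ray)) if per_ray else np.nan
    return {"arclength": s, "width": widths, "truncated": truncated, "path": path}
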