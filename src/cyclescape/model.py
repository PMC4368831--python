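"""Deterministic dynamics of the three-node cell-cycle model.

Drift evaluation, stiff integration, fixed points and stability, the
excitable→limit-cycle bifurcation in the nutrient parameter ``a0``,
limit-cycle detection and parameter sensitivity scans.

The model is excitable at baseline: a stable G1 state P1 (x,y≈0, z high)
coexists with a nearby saddle P2 (the "excited G1"/Start transition);
once past P2 the flow runs through the S-phase vertex P3=(x_max,0,0) and
the early-M vertex P4=(0,y_max,0) before returning to P1.  P3/P4 are
slow-passage vertices of the trajectory, not fixed points of the full
system (the trigger terms ka1·x, ka2·y break exact fixedness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root
from scipy.stats import qmc

from .params import ModelParams, PARAM_NAMES

__all__ = [
    "drift",
    "jacobian",
    "integrate",
    "Trajectory",
    "FixedPointRecord",
    "find_fixed_points",
    "passage_points",
    "locate_bifurcation_a0",
    "detect_limit_cycle",
    "LimitCycle",
    "classify_regime",
    "excited_start",
    "sensitivity_scan",
]


def _check_state(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.shape[-1] != 3:
        raise ValueError("state must have three components (x, y, z)")
    if np.any(s < 0):
        raise ValueError(f"state components must be nonnegative, got {s}")
    return s


def drift(params: ModelParams, s: Sequence[float]) -> np.ndarray:
    """Right-hand side b(x) of the deterministic model.

    dx/dt = x²/(j1²+x²) − k1·x − x·y + a0
    dy/dt = y²/(j2²+y²) − k2·y − y·z + ka1·x
    dz/dt = ks·z²/(j3²+z²) − k3·z − ki·z·x + ka2·y
    """
    s = _check_state(s)
    x, y, z = s[..., 0], s[..., 1], s[..., 2]
    p = params
    bx = x * x / (p.j1 ** 2 + x * x) - p.k1 * x - x * y + p.a0
    by = y * y / (p.j2 ** 2 + y * y) - p.k2 * y - y * z + p.ka1 * x
    bz = p.ks * z * z / (p.j3 ** 2 + z * z) - p.k3 * z - p.ki * z * x + p.ka2 * y
    return np.stack([bx, by, bz], axis=-1)


def jacobian(params: ModelParams, s: Sequence[float]) -> np.ndarray:
    """Analytic Jacobian of the drift at a single state."""
    x, y, z = _check_state(s)
    p = params

    def hill_d(u: float, j: float) -> float:
        return 2.0 * u * j * j / (j * j + u * u) ** 2

    return np.array(
        [
            [hill_d(x, p.j1) - p.k1 - y, -x, 0.0],
            [p.ka1, hill_d(y, p.j2) - p.k2 - z, -y],
            [-p.ki * z, p.ka2, p.ks * hill_d(z, p.j3) - p.k3 - p.ki * x],
        ]
    )


@dataclass
class Trajectory:
    """An integrated orbit: strictly increasing times and (n, 3) states."""

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "x": self.states[:, 0], "y": self.states[:, 1], "z": self.states[:, 2]}
        )


def integrate(
    params: ModelParams,
    s0: Sequence[float],
    t_end: float,
    *,
    n_samples: int = 2000,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the stiff ODE flow from ``s0`` for ``t_end`` time units.

    Each negative term of the drift carries a factor of its own variable
    (plus the constant a0 feeding x), so the nonnegative octant is
    forward-invariant; tiny negative integrator excursions are clipped.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    s0 = _check_state(s0)
    sol = solve_ivp(
        lambda _t, s: drift(params, np.maximum(s, 0.0)),
        (0.0, float(t_end)),
        s0,
        method=method,
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"integration failed: {sol.message}")
    t = np.linspace(0.0, float(t_end), n_samples)
    states = np.clip(sol.sol(t).T, 0.0, None)
    return Trajectory(t, states)


@dataclass
class FixedPointRecord:
    """A root of the drift with its linear stability classification."""

    location: np.ndarray
    eigenvalues: np.ndarray
    stability: str  # "stable" | "saddle" | "unstable"
    label: str = "other"
    residual: float = field(default=0.0)

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


def _structured_starts(params: ModelParams) -> np.ndarray:
    """Self-consistent guesses for the axis-hugging fixed points.

    The biologically relevant roots hug the coordinate axes, where the
    Newton basins from generic interior starts are tiny: the G1-like
    states (x≈a0/k1, z a root of the coupled quadratic), the origin-like
    all-low state, and the checkpoint stall states at high x or high y.
    """
    p = params
    guesses = [[0.0, 0.0, 0.0]]
    x_hat = p.a0 / p.k1
    for _ in range(2):  # one fixed-point iteration refines x̂ against its Hill term
        x_hat = (p.a0 + x_hat * x_hat / (p.j1 ** 2 + x_hat * x_hat)) / p.k1
    c = p.k3 + p.ki * x_hat
    disc = p.ks ** 2 - 4.0 * c ** 2 * p.j3 ** 2
    if disc > 0:
        for z_hat in ((p.ks + np.sqrt(disc)) / (2 * c), (p.ks - np.sqrt(disc)) / (2 * c)):
            guesses.append([x_hat, p.ka1 * x_hat / (p.k2 + z_hat), z_hat])
    guesses.append([x_hat, p.ka1 * x_hat / p.k2, 1e-6])
    # stall states: one module saturated, the others nearly off
    disc_x = 1.0 - 4.0 * p.k1 ** 2 * p.j1 ** 2
    if disc_x > 0:
        x_hi = (1.0 + np.sqrt(disc_x)) / (2 * p.k1)
        guesses.append([x_hi, p.ka1 * x_hi / p.k2, 1e-6])
    disc_y = 1.0 - 4.0 * p.k2 ** 2 * p.j2 ** 2
    if disc_y > 0:
        y_hi = (1.0 + np.sqrt(disc_y)) / (2 * p.k2)
        guesses.append([p.a0 / (p.k1 + y_hi), y_hi, 1e-6])
    return np.array(guesses)


def _classify(eigs: np.ndarray) -> str:
    re = eigs.real
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def find_fixed_points(
    params: ModelParams,
    search_box: Sequence[Sequence[float]] = ((0.0, 6.0),) * 3,
    n_starts: int = 200,
    seed: int = 0,
    tol: float = 1e-11,
    dedup: float = 1e-6,
) -> list[FixedPointRecord]:
    """Multi-start root finding for drift(s)=0 with stability labels.

    Starts are drawn from a Halton sequence over ``search_box`` plus a few
    structured guesses near the coordinate axes (the biologically relevant
    states hug the axes).  Roots closer than ``dedup`` in max-norm are
    merged.  Labels: P1 = stable G1-like (z large, x,y small), P2 = the
    saddle nearest P1.
    """
    lo = np.array([b[0] for b in search_box], float)
    hi = np.array([b[1] for b in search_box], float)
    if np.any(lo < 0):
        raise ValueError("search box must lie in the nonnegative octant")
    starts = qmc.Halton(d=3, seed=seed).random(n_starts) * (hi - lo) + lo
    extra = _structured_starts(params)

    def residual(s: np.ndarray) -> np.ndarray:
        # smooth extension of the drift (Hill terms are even); negatives are
        # filtered afterwards, keeping Newton steps well-behaved near axes
        x, y, z = s
        p = params
        return np.array(
            [
                x * x / (p.j1 ** 2 + x * x) - p.k1 * x - x * y + p.a0,
                y * y / (p.j2 ** 2 + y * y) - p.k2 * y - y * z + p.ka1 * x,
                p.ks * z * z / (p.j3 ** 2 + z * z) - p.k3 * z - p.ki * z * x + p.ka2 * y,
            ]
        )

    roots: list[FixedPointRecord] = []
    for s0 in np.vstack([extra, starts]):
        res = root(residual, s0, method="hybr", tol=tol)
        if not res.success or np.any(res.x < -1e-8):
            continue
        s = np.maximum(res.x, 0.0)
        r = float(np.linalg.norm(drift(params, s)))
        if r > 1e-9:
            continue
        if np.any(s < lo - 1e-9) or np.any(s > hi + 1e-9):
            continue
        if any(np.max(np.abs(s - fp.location)) < dedup for fp in roots):
            continue
        eigs = np.linalg.eigvals(jacobian(params, s))
        roots.append(FixedPointRecord(s, eigs, _classify(eigs), residual=r))

    # label P1 (stable G1-like) and P2 (saddle nearest P1)
    p1 = None
    for fp in roots:
        if fp.is_stable and fp.location[2] > 1.0 and fp.location[0] < 0.5 and fp.location[1] < 0.5:
            fp.label = "P1"
            p1 = fp
    if p1 is not None:
        saddles = [fp for fp in roots if fp.stability == "saddle"]
        if saddles:
            nearest = min(saddles, key=lambda fp: np.linalg.norm(fp.location - p1.location))
            nearest.label = "P2"
    return sorted(roots, key=lambda fp: tuple(fp.location))


def fixed_points_report(records: Sequence[FixedPointRecord]) -> str:
    """Structured text table of fixed-point records (one per line)."""
    lines = ["# label  x  y  z  stability  re(eig1) re(eig2) re(eig3)  |b|"]
    for fp in records:
        x, y, z = fp.location
        re = np.sort(fp.eigenvalues.real)
        lines.append(
            f"{fp.label:5s}  {x:.6g} {y:.6g} {z:.6g}  {fp.stability:8s}  "
            f"{re[0]:.4g} {re[1]:.4g} {re[2]:.4g}  {fp.residual:.2e}"
        )
    return "\n".join(lines)


def excited_start(params: ModelParams, delta: float = 0.02) -> np.ndarray:
    """A state just past the Start transition (P2), heading down the canal.

    Displaces P2 by ``delta`` along its unstable eigendirection (oriented
    toward growing x).  Falls back to a small-x kick if no saddle exists.
    """
    fps = find_fixed_points(params, n_starts=80, seed=1)
    p2 = next((fp for fp in fps if fp.label == "P2"), None)
    if p2 is None:
        p1 = next((fp for fp in fps if fp.label == "P1"), None)
        base = p1.location if p1 is not None else np.array([0.0, 0.0, 4.3])
        return base + np.array([0.1, 0.0, 0.0])
    J = jacobian(params, p2.location)
    w, v = np.linalg.eig(J)
    u = np.real(v[:, np.argmax(w.real)])
    if u[0] < 0:
        u = -u
    return np.clip(p2.location + delta * u, 0.0, None)


def passage_points(params: ModelParams, t_end: float = 400.0) -> dict[str, np.ndarray]:
    """Locate the S-phase and early-M vertices P3=(x_max,0,0), P4=(0,y_max,0).

    x_max and y_max are the maxima of x and y along the excited trajectory
    (for excitable parameters) or along the limit cycle (otherwise); the
    trigger couplings keep these slow-passage vertices slightly off the
    idealized subsystem roots.
    """
    traj = integrate(params, excited_start(params), t_end, n_samples=8000)
    x_max = float(traj.states[:, 0].max())
    y_max = float(traj.states[:, 1].max())
    # a stalled trajectory (checkpoint hold) never visits the later vertex;
    # fall back to the idealized single-module saturation root there
    def _subsystem_hi(k: float, j: float) -> float:
        disc = 1.0 - 4.0 * k * k * j * j
        return (1.0 + np.sqrt(disc)) / (2.0 * k) if disc > 0 else 1.0 / k
    if x_max < 1.0:
        x_max = _subsystem_hi(params.k1, params.j1)
    if y_max < 1.0:
        y_max = _subsystem_hi(params.k2, params.j2)
    return {"P3": np.array([x_max, 0.0, 0.0]), "P4": np.array([0.0, y_max, 0.0])}


def _has_g1_state(params: ModelParams, n_starts: int = 60, seed: int = 3) -> bool:
    """Predicate: a stable fixed point with z > 1 and x, y < 0.5 exists."""
    fps = find_fixed_points(params, n_starts=n_starts, seed=seed)
    return any(fp.label == "P1" for fp in fps)


def locate_bifurcation_a0(
    params_template: ModelParams,
    a0_range: tuple[float, float] = (0.001, 0.01),
    tolerance: float = 1e-5,
) -> float:
    """Bisection for the critical a0 where the stable G1 state annihilates.

    Below a0* the system is excitable (stable G1 + saddle); above, the
    G1 state has merged with the saddle and the flow settles onto a limit
    cycle.  Raises if the predicate does not change across the bracket.
    """
    lo, hi = a0_range
    has_lo = _has_g1_state(params_template.with_updates(a0=lo))
    has_hi = _has_g1_state(params_template.with_updates(a0=hi))
    if has_lo == has_hi:
        raise ValueError(
            f"a0 range {a0_range} does not bracket the bifurcation "
            f"(stable G1 at both ends: {has_lo})"
        )
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if _has_g1_state(params_template.with_updates(a0=mid)) == has_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class LimitCycle:
    period: float
    samples: np.ndarray  # (n, 3) one period, uniformly sampled in time

    def nearest_point(self, s: Sequence[float]) -> np.ndarray:
        d = np.linalg.norm(self.samples - np.asarray(s), axis=1)
        return self.samples[int(np.argmin(d))]


def detect_limit_cycle(
    params: ModelParams,
    s0: Sequence[float] | None = None,
    t_transient: float = 1500.0,
    t_observe: float = 1500.0,
    rtol: float = 1e-9,
    n_cycle_samples: int = 400,
) -> LimitCycle | None:
    """Poincaré-section recurrence detection after a transient.

    Returns the period and one sampled cycle, or ``None`` when the
    trajectory converges to a fixed point (no section crossings, or the
    orbit collapses).  The section is the plane x = x_ref (midrange of the
    observed orbit) crossed with dx/dt > 0.
    """
    if s0 is None:
        s0 = [1.0, 0.1, 0.1]
    pre = integrate(params, s0, t_transient, n_samples=500, rtol=rtol)
    start = pre.final_state
    # converged to a point?
    if np.linalg.norm(drift(params, start)) < 1e-7:
        return None
    sol = solve_ivp(
        lambda _t, s: drift(params, np.maximum(s, 0.0)),
        (0.0, t_observe),
        start,
        method="LSODA",
        rtol=rtol,
        atol=1e-12,
        dense_output=True,
        max_step=1.0,
    )
    t = np.linspace(0, t_observe, 20000)
    Y = sol.sol(t).T
    span = Y.max(axis=0) - Y.min(axis=0)
    if np.all(span < 1e-4):
        return None
    x_ref = 0.5 * (Y[:, 0].max() + Y[:, 0].min())
    fx = Y[:, 0] - x_ref
    crossings = np.where((fx[:-1] < 0) & (fx[1:] >= 0))[0]
    if len(crossings) < 3:
        return None
    # refine crossing times by linear interpolation
    tc = t[crossings] + (t[crossings + 1] - t[crossings]) * (-fx[crossings]) / (
        fx[crossings + 1] - fx[crossings]
    )
    periods = np.diff(tc)
    period = float(np.median(periods))
    if period <= 0 or np.std(periods[-3:]) > 0.05 * period:
        return None
    ts = np.linspace(tc[-2], tc[-2] + period, n_cycle_samples, endpoint=False)
    return LimitCycle(period, np.clip(sol.sol(ts).T, 0.0, None))


def classify_regime(params: ModelParams) -> str:
    """One of ``excitable`` (stable G1 exists), ``limit_cycle``, ``other``."""
    if _has_g1_state(params):
        return "excitable"
    if detect_limit_cycle(params) is not None:
        return "limit_cycle"
    return "other"


def sensitivity_scan(
    params: ModelParams,
    perturbation_fraction: float = 0.20,
    well_depth_fn: Callable[[ModelParams], float] | None = None,
    parameters: Sequence[str] = PARAM_NAMES,
) -> pd.DataFrame:
    """±perturbation runs for each parameter: regime class and δS well depth.

    ``well_depth_fn`` maps a parameter set to the G1 well depth ΔS (e.g. a
    quasi-potential barrier from the landscape module); δS is the change
    relative to the unperturbed depth.  Failures of individual runs are
    recorded as missing entries and the scan continues.
    """
    rows = []
    base_depth = None
    if well_depth_fn is not None:
        base_depth = well_depth_fn(params)
    for name in parameters:
        for direction, sign in (("up", +1), ("down", -1)):
            value = getattr(params, name) * (1 + sign * perturbation_fraction)
            row = {"parameter": name, "direction": direction, "value": value}
            try:
                p = params.with_updates(**{name: value})
                row["regime"] = classify_regime(p)
                if well_depth_fn is not None:
                    row["delta_S"] = well_depth_fn(p) - base_depth
            except Exception as exc:  # individual failure -> missing entry
                row.setdefault("regime", None)
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
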