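"""Exact Gillespie simulation and finite-volume landscape estimation.

This module is the package's synthetic-data generator: it produces the
stochastic trajectories and residence-time statistics that the
finite-volume (−ln P̂) analysis assumes.  The inner loops are numba
kernels implementing the direct SSA (exponential waiting times from the
total propensity; channel chosen proportionally); runs are bitwise
reproducible given a seed, with per-replicate substreams derived from a
master seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .landscape import LandscapeGrid
from .network import ReactionNetwork

__all__ = [
    "JumpTrajectory",
    "OccupancyHistogram",
    "simulate",
    "stationary_histogram",
    "finite_volume_landscape",
    "mean_exit_time",
    "ExitTimes",
    "exit_time_volume_scaling",
]


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _props(X, V, ptype, pc, pj, pi1, pi2, out):
    for m in range(len(ptype)):
        t = ptype[m]
        if t == 0:
            out[m] = pc[m] * V
        elif t == 1:
            out[m] = pc[m] * X[pi1[m]]
        elif t == 2:
            out[m] = pc[m] * X[pi1[m]] * X[pi2[m]] / V
        else:
            u = X[pi1[m]]
            out[m] = pc[m] * V * u * u / ((pj[m] * V) ** 2 + u * u)


@njit(cache=True)
def _ssa_record(nu, ptype, pc, pj, pi1, pi2, V, x0, t_end, seed, max_events):
    np.random.seed(seed)
    dim = len(x0)
    X = x0.copy()
    a = np.zeros(len(ptype))
    times = np.empty(max_events)
    states = np.empty((max_events, dim))
    t = 0.0
    n = 0
    absorbed = False
    while t < t_end and n < max_events:
        _props(X, V, ptype, pc, pj, pi1, pi2, a)
        a0 = a.sum()
        if a0 <= 0.0:
            absorbed = True
            break
        t += -np.log(np.random.random()) / a0
        if t > t_end:
            break
        r = np.random.random() * a0
        c = 0.0
        m = 0
        for mm in range(len(a)):
            c += a[mm]
            if r < c:
                m = mm
                break
        for d in range(dim):
            X[d] += nu[m, d]
            if X[d] < 0:
                X[d] = 0
        times[n] = t
        states[n] = X
        n += 1
    return times[:n], states[:n], absorbed


@njit(cache=True)
def _ssa_hist(
    nu, ptype, pc, pj, pi1, pi2, V, x0, t_total, seed,
    edges0, edges1, edges2, restart_on, rs_state, g1_lo, g1_hi, ex_c, ex_r,
):
    np.random.seed(seed)
    dim = len(x0)
    X = x0.copy()
    a = np.zeros(len(ptype))
    nb0, nb1, nb2 = len(edges0) - 1, len(edges1) - 1, len(edges2) - 1
    H = np.zeros((nb0, nb1, nb2))
    t = 0.0
    nev = 0
    while t < t_total:
        _props(X, V, ptype, pc, pj, pi1, pi2, a)
        a0 = a.sum()
        if a0 <= 0.0:
            break
        dt = -np.log(np.random.random()) / a0
        if t + dt > t_total:
            dt = t_total - t
        x = X[0] / V
        y = X[1] / V if dim > 1 else 0.0
        z = X[2] / V if dim > 2 else 0.0
        excl = False
        if ex_r > 0.0:
            d2 = (x - ex_c[0]) ** 2 + (y - ex_c[1]) ** 2 + (z - ex_c[2]) ** 2
            excl = d2 < ex_r * ex_r
        if not excl:
            i = np.searchsorted(edges0, x, side="right") - 1
            j = np.searchsorted(edges1, y, side="right") - 1
            k = np.searchsorted(edges2, z, side="right") - 1
            if i == nb0 and x == edges0[nb0]:
                i = nb0 - 1
            if j == nb1 and y == edges1[nb1]:
                j = nb1 - 1
            if k == nb2 and z == edges2[nb2]:
                k = nb2 - 1
            if 0 <= i < nb0 and 0 <= j < nb1 and 0 <= k < nb2:
                H[i, j, k] += dt
        t += dt
        if t >= t_total:
            break
        nev += 1
        r = np.random.random() * a0
        c = 0.0
        m = 0
        for mm in range(len(a)):
            c += a[mm]
            if r < c:
                m = mm
                break
        for d in range(dim):
            X[d] += nu[m, d]
            if X[d] < 0:
                X[d] = 0
        if restart_on and dim == 3:
            x = X[0] / V
            y = X[1] / V
            z = X[2] / V
            if (
                g1_lo[0] < x < g1_hi[0]
                and g1_lo[1] < y < g1_hi[1]
                and g1_lo[2] < z < g1_hi[2]
            ):
                for d in range(dim):
                    X[d] = rs_state[d]
    return H, nev


@njit(cache=True)
def _ssa_advance(nu, ptype, pc, pj, pi1, pi2, V, x0, t_end, seed):
    """Advance the state without recording (used for burn-in)."""
    np.random.seed(seed)
    X = x0.copy()
    a = np.zeros(len(ptype))
    t = 0.0
    while t < t_end:
        _props(X, V, ptype, pc, pj, pi1, pi2, a)
        a0 = a.sum()
        if a0 <= 0.0:
            break
        t += -np.log(np.random.random()) / a0
        if t >= t_end:
            break
        r = np.random.random() * a0
        c = 0.0
        m = 0
        for mm in range(len(a)):
            c += a[mm]
            if r < c:
                m = mm
                break
        for d in range(len(X)):
            X[d] += nu[m, d]
            if X[d] < 0:
                X[d] = 0
    return X


@njit(cache=True)
def _ssa_exit(nu, ptype, pc, pj, pi1, pi2, V, x0, species, thresh, upward, t_cap, seed):
    np.random.seed(seed)
    X = x0.copy()
    a = np.zeros(len(ptype))
    t = 0.0
    while t < t_cap:
        if upward:
            if X[species] >= thresh:
                return t
        else:
            if X[species] <= thresh:
                return t
        _props(X, V, ptype, pc, pj, pi1, pi2, a)
        a0 = a.sum()
        if a0 <= 0.0:
            return -1.0
        t += -np.log(np.random.random()) / a0
        r = np.random.random() * a0
        c = 0.0
        m = 0
        for mm in range(len(a)):
            c += a[mm]
            if r < c:
                m = mm
                break
        for d in range(len(X)):
            X[d] += nu[m, d]
            if X[d] < 0:
                X[d] = 0
    return -1.0


# ---------------------------------------------------------------------------
# public API


@dataclass
class JumpTrajectory:
    """Event stream of an exact SSA run (counts; concentration = X/V)."""

    event_times: np.ndarray
    states: np.ndarray
    rng_seed: int
    V: float
    absorbed: bool = False

    def concentrations(self) -> np.ndarray:
        return self.states / self.V


def _kernel_args(network: ReactionNetwork):
    k = network.kernel_arrays()
    return k["nu"], k["ptype"], k["pc"], k["pj"], k["pi1"], k["pi2"]


def simulate(
    network: ReactionNetwork,
    s0: Sequence[float],
    t_end: float,
    seed: int,
    max_events: int = 2_000_000,
) -> JumpTrajectory:
    """Exact SSA (direct method) from counts ``s0`` until ``t_end``.

    The returned trajectory stores the initial state at time 0 followed by
    the post-event states; identical arguments give identical streams.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    x0 = np.asarray(s0, dtype=float)
    if np.any(x0 < 0) or np.any(x0 != np.round(x0)):
        raise ValueError("initial counts must be nonnegative integers")
    times, states, absorbed = _ssa_record(
        *_kernel_args(network), network.V, x0.copy(), float(t_end), int(seed) & 0x7FFFFFFF,
        int(max_events),
    )
    times = np.concatenate([[0.0], times])
    states = np.vstack([x0, states])
    return JumpTrajectory(times, states, int(seed), network.V, bool(absorbed))


def trajectory_at_times(traj: JumpTrajectory, t: np.ndarray) -> np.ndarray:
    """Piecewise-constant interpolation of the event stream (counts)."""
    t = np.asarray(t, dtype=float)
    idx = np.clip(np.searchsorted(traj.event_times, t, side="right") - 1, 0, None)
    return traj.states[idx]


@dataclass
class OccupancyHistogram:
    """Residence-time-weighted occupancy over concentration bins."""

    counts: np.ndarray  # 3-D array of residence times (time units)
    bin_edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    total_weight: float
    V: float
    seed: int
    meta: dict = field(default_factory=dict)

    def normalized(self) -> np.ndarray:
        return self.counts / self.total_weight


def stationary_histogram(
    network: ReactionNetwork,
    s0: Sequence[float],
    t_total: float,
    bins: int | Sequence[np.ndarray] = 60,
    seed: int = 0,
    burn_in: float = 0.0,
    bounds: tuple[float, float] = (0.0, 6.0),
    restart_rule: dict | None = None,
) -> OccupancyHistogram:
    """Residence-time histogram over concentration space.

    ``restart_rule`` implements the conditioned (reinjected) statistics
    used for the excitable regime, where the global stationary law piles
    up in the G1 basin: whenever the trajectory enters the G1 box the
    state is reset to ``restart_state`` (counts), and residence inside an
    exclusion ball around the G1 state is not accumulated.  Keys:
    ``g1_lo``/``g1_hi`` (concentration box), ``restart_state`` (counts),
    ``exclude_center``/``exclude_radius`` (concentration ball).
    """
    if isinstance(bins, int):
        edges = [np.linspace(bounds[0], bounds[1], bins + 1)] * 3
    else:
        edges = [np.asarray(e, dtype=float) for e in bins]
    while len(edges) < 3:
        edges.append(np.array([0.0, np.inf]))
    rr = restart_rule or {}
    restart_on = bool(rr)
    rs_state = np.asarray(rr.get("restart_state", np.zeros(3)), dtype=float)
    g1_lo = np.asarray(rr.get("g1_lo", [-1.0, -1.0, 2.0]), dtype=float)
    g1_hi = np.asarray(rr.get("g1_hi", [0.2, 0.2, np.inf]), dtype=float)
    ex_c = np.asarray(rr.get("exclude_center", np.zeros(3)), dtype=float)
    ex_r = float(rr.get("exclude_radius", -1.0))
    x0 = np.asarray(s0, dtype=float)

    if burn_in > 0:
        x0 = _ssa_advance(
            *_kernel_args(network), network.V, x0.copy(), float(burn_in),
            (int(seed) ^ 0x5D2E1) & 0x7FFFFFFF,
        )
    H, nev = _ssa_hist(
        *_kernel_args(network), network.V, x0.copy(), float(t_total),
        int(seed) & 0x7FFFFFFF, edges[0], edges[1], edges[2],
        restart_on, rs_state, g1_lo, g1_hi, ex_c, ex_r,
    )
    total = float(H.sum())
    if total <= 0:
        raise RuntimeError("empty histogram: no residence accumulated after burn-in")
    return OccupancyHistogram(
        H, tuple(edges), total, network.V, int(seed),
        meta={"t_total": t_total, "burn_in": burn_in, "events": int(nev),
              "conditioned": restart_on},
    )


def finite_volume_landscape(hist: OccupancyHistogram) -> LandscapeGrid:
    """−ln P̂ over the occupied bins; empty bins are missing (NaN).

    The WKB correspondence P ∝ exp(−V·S) makes −ln P̂ the finite-volume
    energy landscape on the scale V·S.
    """
    P = hist.normalized()
    with np.errstate(divide="ignore"):
        S = np.where(P > 0, -np.log(P), np.nan)
    centers = tuple(0.5 * (e[1:] + e[:-1]) for e in hist.bin_edges)
    # drop degenerate axes (1-D/2-D systems padded to 3-D)
    keep = [k for k, c in enumerate(centers) if len(c) > 1]
    S = np.squeeze(S, axis=tuple(k for k in range(3) if k not in keep)) if len(keep) < 3 else S
    axes = tuple(centers[k] for k in keep)
    return LandscapeGrid(
        S, axes, None,
        {"kind": "finite_volume", "V": hist.V, "seed": hist.seed, **hist.meta},
    )


@dataclass
class ExitTimes:
    times: np.ndarray  # first-passage times of uncensored reps
    n_censored: int
    mean: float
    ci: tuple[float, float]  # bootstrap 95% CI of the mean


def mean_exit_time(
    network: ReactionNetwork,
    basin: dict,
    n_reps: int = 100,
    seed: int = 0,
    t_cap: float = 1e7,
) -> ExitTimes:
    """First-passage times out of a basin, with a bootstrap CI of the mean.

    ``basin`` keys: ``start`` (counts), ``species`` (index), ``threshold``
    (counts), ``direction`` ("up" exit when X ≥ threshold, "down" when
    X ≤ threshold).  Replicates exceeding ``t_cap`` are censored and
    reported, not silently dropped.
    """
    x0 = np.asarray(basin["start"], dtype=float)
    species = int(basin["species"])
    thresh = float(basin["threshold"])
    upward = basin.get("direction", "up") == "up"
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) & 0x7FFFFFFF
    args = _kernel_args(network)
    times = np.array(
        [
            _ssa_exit(*args, network.V, x0.copy(), species, thresh, upward, t_cap, int(s))
            for s in seeds
        ]
    )
    censored = int(np.sum(times < 0))
    good = times[times >= 0]
    if good.size == 0:
        return ExitTimes(good, censored, np.nan, (np.nan, np.nan))
    rng = np.random.default_rng(seed + 1)
    boots = rng.choice(good, size=(400, good.size), replace=True).mean(axis=1)
    return ExitTimes(
        good, censored, float(good.mean()),
        (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))),
    )


def exit_time_volume_scaling(
    make_network,
    volumes: Sequence[float],
    basin_for_volume,
    n_reps: int = 100,
    seed: int = 0,
    prefactor_exponent: float = -0.5,
) -> dict:
    """Regression of ln(mean exit time) against V across volumes.

    The asymptotic exit law is τ ≍ C·V^γ·exp(V·ΔS); for the 1-D
    birth–death threshold crossing γ = −1/2 exactly (Stirling on the
    closed-form mean first-passage sum), so the response variable is
    ln(mean τ) − γ·ln V and the fitted slope estimates ΔS.  Returns the
    slope, its t-based 95% CI, and R² of the (uncorrected) linearity.
    """
    means = []
    for i, V in enumerate(volumes):
        net = make_network(V)
        res = mean_exit_time(net, basin_for_volume(V), n_reps=n_reps, seed=seed + 7919 * i)
        means.append(res.mean)
    Vs = np.asarray(volumes, dtype=float)
    L_raw = np.log(means)
    L = L_raw - prefactor_exponent * np.log(Vs)
    A = np.vstack([Vs, np.ones_like(Vs)]).T
    coef, resid, _, _ = np.linalg.lstsq(A, L, rcond=None)
    dof = len(Vs) - 2
    sxx = np.sum((Vs - Vs.mean()) ** 2)
    se = float(np.sqrt(resid[0] / dof / sxx)) if dof > 0 and resid.size else np.nan
    # linearity measured on the raw response
    coef_raw, resid_raw, _, _ = np.linalg.lstsq(A, L_raw, rcond=None)
    ss_tot = float(np.sum((L_raw - L_raw.mean()) ** 2))
    r2 = 1.0 - float(resid_raw[0]) / ss_tot if resid_raw.size else 1.0
    from scipy.stats import t as _t

    half = _t.ppf(0.975, dof) * se if dof > 0 else np.inf
    return {
        "slope": float(coef[0]),
        "intercept": float(coef[1]),
        "ci": (float(coef[0] - half), float(coef[0] + half)),
        "r2": r2,
        "mean_times": np.asarray(means),
        "volumes": Vs,
    }
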