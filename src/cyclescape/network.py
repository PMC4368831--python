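"""Volume-scaled jump-process translation of the deterministic model.

Each additive term of the rate equations becomes one reaction channel at
system size (volume) V: positive terms are birth channels (ν = +e_k),
negative terms death channels (ν = −e_k), twelve channels in total.  For
the x equation the propensities are

    a1(X) = V·X²/((j1·V)² + X²),  a2(X) = k1·X,
    a3(X) = X·Y/V,                a4(X) = a0·V,

and the y/z equations are treated by exact analogy.  With this scaling
Σ_j ν_j·a_j(V·x)/V reproduces the deterministic drift b(x) identically
(not just asymptotically), which the tests exploit as an invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import drift as _model_drift
from .params import ModelParams

__all__ = [
    "ReactionChannel",
    "ReactionNetwork",
    "build_network",
    "birth_death_network",
    "mean_field_drift",
    "hamiltonian",
]

# propensity rule kinds understood by the SSA kernels
CONST, LINEAR, BILINEAR, HILL = 0, 1, 2, 3


@dataclass(frozen=True)
class ReactionChannel:
    """One reaction: state change ν, rule kind and parameters.

    ``kind`` selects the propensity rule (in molecule counts at volume V):

    * ``CONST``:     c·V
    * ``LINEAR``:    c·X[i]
    * ``BILINEAR``:  c·X[i]·X[j]/V
    * ``HILL``:      c·V·X[i]²/((j·V)² + X[i]²)

    ``source_term`` documents which additive term of which equation the
    channel encodes.  Rules accept real-valued arguments so the same
    channel serves integer-count SSA and the continuum Hamiltonian.
    """

    nu: tuple[int, ...]
    kind: int
    coeff: float
    hill_j: float
    i1: int
    i2: int
    source_term: str

    def propensity(self, X: np.ndarray, V: float) -> np.ndarray:
        """Propensity at counts ``X`` (last axis = species), volume V."""
        X = np.asarray(X, dtype=float)
        if self.kind == CONST:
            return np.broadcast_to(self.coeff * V, X.shape[:-1]).copy()
        if self.kind == LINEAR:
            return self.coeff * X[..., self.i1]
        if self.kind == BILINEAR:
            return self.coeff * X[..., self.i1] * X[..., self.i2] / V
        u = X[..., self.i1]
        return self.coeff * V * u * u / ((self.hill_j * V) ** 2 + u * u)

    def concentration_rate(self, s: np.ndarray) -> np.ndarray:
        """Concentration-scale propensity a_j(x) = a_j(V·x)/V (V-independent)."""
        return self.propensity(np.asarray(s, dtype=float), 1.0)


@dataclass(frozen=True)
class ReactionNetwork:
    """An ordered set of channels with parameters and system size."""

    channels: tuple[ReactionChannel, ...]
    params: ModelParams | None
    V: float
    n_species: int

    def __post_init__(self) -> None:
        if not self.V > 0:
            raise ValueError("system size V must be positive")

    @property
    def nu_matrix(self) -> np.ndarray:
        return np.array([c.nu for c in self.channels], dtype=np.int64)

    def propensities(self, X: Sequence[float]) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.stack([c.propensity(X, self.V) for c in self.channels], axis=-1)

    def birth_death_rates(self, s: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        """Aggregate concentration-scale birth/death rates per species.

        Returns ``(B, D)`` with shape ``s.shape[:-1] + (n_species,)``:
        B_k sums channels with ν = +e_k, D_k those with ν = −e_k.
        """
        s = np.asarray(s, dtype=float)
        B = np.zeros(s.shape[:-1] + (self.n_species,))
        D = np.zeros_like(B)
        for c in self.channels:
            k = int(np.flatnonzero(c.nu)[0])
            rate = c.concentration_rate(s)
            if c.nu[k] > 0:
                B[..., k] += rate
            else:
                D[..., k] += rate
        return B, D

    def kernel_arrays(self) -> dict[str, np.ndarray]:
        """Flat array encoding consumed by the numba SSA kernels."""
        return {
            "nu": self.nu_matrix,
            "ptype": np.array([c.kind for c in self.channels], dtype=np.int64),
            "pc": np.array([c.coeff for c in self.channels], dtype=float),
            "pj": np.array([c.hill_j for c in self.channels], dtype=float),
            "pi1": np.array([c.i1 for c in self.channels], dtype=np.int64),
            "pi2": np.array([c.i2 for c in self.channels], dtype=np.int64),
        }

    def describe(self) -> str:
        """Structured text description (one channel per line) for audit."""
        kinds = {CONST: "const", LINEAR: "linear", BILINEAR: "bilinear", HILL: "hill"}
        lines = [f"# reaction network: V={self.V}, species={self.n_species}"]
        for i, c in enumerate(self.channels):
            lines.append(
                f"{i:2d}  nu={list(c.nu)}  {kinds[c.kind]:8s} coeff={c.coeff:g} "
                f"hill_j={c.hill_j:g} i1={c.i1} i2={c.i2}  # {c.source_term}"
            )
        return "\n".join(lines)


def _e(k: int, sign: int, dim: int = 3) -> tuple[int, ...]:
    v = [0] * dim
    v[k] = sign
    return tuple(v)


def build_network(params: ModelParams, V: float) -> ReactionNetwork:
    """The 12-channel jump process of the three-node model at volume V."""
    if not V > 0:
        raise ValueError("system size V must be positive")
    p = params
    ch = [
        # x equation, terms 1-4
        ReactionChannel(_e(0, +1), HILL, 1.0, p.j1, 0, 0, "eq-x hill feedback"),
        ReactionChannel(_e(0, -1), LINEAR, p.k1, 0.0, 0, 0, "eq-x degradation k1·x"),
        ReactionChannel(_e(0, -1), BILINEAR, 1.0, 0.0, 0, 1, "eq-x repression x·y"),
        ReactionChannel(_e(0, +1), CONST, p.a0, 0.0, 0, 0, "eq-x nutrient a0"),
        # y equation
        ReactionChannel(_e(1, +1), HILL, 1.0, p.j2, 1, 0, "eq-y hill feedback"),
        ReactionChannel(_e(1, -1), LINEAR, p.k2, 0.0, 1, 0, "eq-y degradation k2·y"),
        ReactionChannel(_e(1, -1), BILINEAR, 1.0, 0.0, 1, 2, "eq-y repression y·z"),
        ReactionChannel(_e(1, +1), LINEAR, p.ka1, 0.0, 0, 0, "eq-y trigger ka1·x"),
        # z equation
        ReactionChannel(_e(2, +1), HILL, p.ks, p.j3, 2, 0, "eq-z hill feedback ks"),
        ReactionChannel(_e(2, -1), LINEAR, p.k3, 0.0, 2, 0, "eq-z degradation k3·z"),
        ReactionChannel(_e(2, -1), BILINEAR, p.ki, 0.0, 2, 0, "eq-z inhibition ki·z·x"),
        ReactionChannel(_e(2, +1), LINEAR, p.ka2, 0.0, 1, 0, "eq-z trigger ka2·y"),
    ]
    return ReactionNetwork(tuple(ch), params, float(V), 3)


def birth_death_network(birth: float, death_rate: float, V: float) -> ReactionNetwork:
    """1-D test system: birth at rate c·V, death at rate k·X.

    Stationary law is Poisson(c·V/k); the quasi-potential has the closed
    form S(x) = x·ln(k·x/c) − x + c/k, which the action tests use as an
    analytic oracle.
    """
    ch = (
        ReactionChannel((1,), CONST, birth, 0.0, 0, 0, "birth c"),
        ReactionChannel((-1,), LINEAR, death_rate, 0.0, 0, 0, "death k·x"),
    )
    return ReactionNetwork(ch, None, float(V), 1)


def mean_field_drift(network: ReactionNetwork, s: Sequence[float]) -> np.ndarray:
    """Σ_j ν_j·a_j(V·x)/V — identical to the ODE drift for this scaling."""
    B, D = network.birth_death_rates(s)
    return B - D


def hamiltonian(network: ReactionNetwork, s: Sequence[float], p: Sequence[float]) -> float:
    """Large-deviation Hamiltonian H(x,p) = Σ_j a_j(x)·(exp(p·ν_j) − 1)."""
    B, D = network.birth_death_rates(s)
    p = np.asarray(p, dtype=float)
    arg = np.clip(p, -500.0, 500.0)
    e = np.exp(arg)
    return float(np.sum(B * (e - 1.0) + D * (1.0 / e - 1.0), axis=-1).sum())


def _consistency_check(params: ModelParams) -> None:  # pragma: no cover - dev aid
    net = build_network(params, 100.0)
    s = np.array([0.5, 0.2, 0.3])
    assert np.allclose(mean_field_drift(net, s), _model_drift(params, s))
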