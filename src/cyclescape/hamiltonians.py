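"""Large-deviation Hamiltonians and the geometric action integrand.

Two noise models share one interface:

* intrinsic (reaction-network) noise — ``JumpHamiltonian`` with
  H(x,p) = Σ_k B_k(x)(e^{p_k}−1) + D_k(x)(e^{−p_k}−1), where B_k/D_k are
  the aggregated birth/death rates per species (every channel of the
  model changes exactly one species by ±1, so H separates per
  coordinate);
* extrinsic additive white noise — ``AdditiveNoiseHamiltonian`` with
  H(x,p) = p·b(x) + |p|²/2.

Both expose the *geometric* (Maupertuis, time-free) Lagrangian

    ℓ(x, û) = max{ p·û : H(x,p) ≤ 0 },

the support function of the convex zero-sublevel set of H in momentum.
Line integrals of ℓ over a curve give the Freidlin–Wentzell action of the
optimally-timed traversal; ℓ = 0 exactly along the deterministic flow.
For the separable jump Hamiltonian the maximizer has a per-coordinate
closed form given the Lagrange multiplier λ of the constraint
(B_k e^{p_k} − D_k e^{−p_k} = λ·û_k), leaving a single scalar root-solve
in λ; for additive noise ℓ(x,û) = |b(x)| − û·b(x) in closed form.
"""

from __future__ import annotations

from typing import Callable, Protocol, Sequence

import numpy as np

from .network import ReactionNetwork

__all__ = ["HamiltonianSpec", "JumpHamiltonian", "AdditiveNoiseHamiltonian"]

_TINY = 1e-300


class HamiltonianSpec(Protocol):
    """Interface consumed by the action and landscape modules."""

    dim: int

    def hamiltonian(self, x: np.ndarray, p: np.ndarray) -> np.ndarray: ...

    def dH_dp(self, x: np.ndarray, p: np.ndarray) -> np.ndarray: ...

    def drift(self, x: np.ndarray) -> np.ndarray: ...

    def geometric_lagrangian(self, x: np.ndarray, u: np.ndarray) -> np.ndarray: ...


class JumpHamiltonian:
    """Intrinsic-noise Hamiltonian of a one-step (birth/death) network.

    ``rates(x) -> (B, D)`` must return aggregated per-species birth and
    death rates on the concentration scale, vectorized over leading axes.
    """

    kind = "intrinsic_jump"

    def __init__(self, rates: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]], dim: int):
        self._rates = rates
        self.dim = dim

    @classmethod
    def from_network(cls, network: ReactionNetwork) -> "JumpHamiltonian":
        return cls(network.birth_death_rates, network.n_species)

    def rates(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        B, D = self._rates(np.asarray(x, dtype=float))
        return np.asarray(B, float), np.asarray(D, float)

    def drift(self, x: np.ndarray) -> np.ndarray:
        B, D = self.rates(x)
        return B - D

    def hamiltonian(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        B, D = self.rates(x)
        e = np.exp(np.clip(np.asarray(p, float), -500, 500))
        return np.sum(B * (e - 1.0) + D * (1.0 / e - 1.0), axis=-1)

    def dH_dp(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        B, D = self.rates(x)
        e = np.exp(np.clip(np.asarray(p, float), -500, 500))
        return B * e - D / e

    # -- geometric Lagrangian ------------------------------------------------

    def _constraint_value(
        self, lam: np.ndarray, B: np.ndarray, D: np.ndarray, U: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """H at the boundary point with outward normal û, for multiplier λ.

        Returns (H value, e^{p_k} array).  Coordinates with û_k = 0 sit at
        their per-coordinate minimum, contributing −(√B_k − √D_k)² (the
        cost rate of holding that species still against its net flux).
        """
        c = lam[..., None] * U
        hasB = B > _TINY
        # B>0: from B·e^p − D·e^{−p} = c, e^p = (c + sqrt(c² + 4BD)) / (2B)
        with np.errstate(over="ignore", invalid="ignore"):
            E = np.where(
                hasB, (c + np.sqrt(c * c + 4.0 * B * D)) / np.where(hasB, 2.0 * B, 1.0), 1.0
            )
        E = np.clip(np.nan_to_num(E, nan=1.0, posinf=1e300), _TINY, 1e300)
        h_gen = B * (E - 1.0) + D / E - D
        # B=0, û<0: e^{−p} = λ|û|/D exactly, term = λ|û| − D
        h_b0_neg = lam[..., None] * (-U) - D
        # B=0, û=0: suppressing a pure-death species costs D; (B=0, û>0 is infeasible,
        # masked upstream)
        h = np.where(hasB, h_gen, np.where(U < 0, h_b0_neg, -D))
        return np.sum(h, axis=-1), E

    def geometric_lagrangian(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        """ℓ(x, û) per row; û rows should be unit vectors.

        Infeasible moves (a direction component with no supporting channel,
        e.g. growth of a species with zero birth rate) return +inf.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        U = np.atleast_2d(np.asarray(u, dtype=float))
        x, U = np.broadcast_arrays(x, U)
        B, D = self.rates(x)
        n = x.shape[0]
        out = np.full(n, np.inf)
        feasible = ~(np.any((U > 0) & (B <= _TINY), axis=-1) | np.any((U < 0) & (D <= _TINY), axis=-1))
        if not feasible.any():
            return out
        B, D, U = B[feasible], D[feasible], U[feasible]
        m = B.shape[0]

        def g(lam: np.ndarray) -> np.ndarray:
            return self._constraint_value(lam, B, D, U)[0]

        hi = np.ones(m)
        for _ in range(60):
            bad = g(hi) < 0
            if not bad.any():
                break
            hi[bad] *= 2.0
            if hi.max() > 1e12:
                break
        dead = g(hi) < 0  # momentum solve diverged (cost effectively infinite)
        lo = np.zeros(m)
        for _ in range(64):
            mid = 0.5 * (lo + hi)
            neg = g(mid) < 0
            lo = np.where(neg, mid, lo)
            hi = np.where(neg, hi, mid)
        lam = 0.5 * (lo + hi)
        _, E = self._constraint_value(lam, B, D, U)
        hasB = B > _TINY
        p = np.where(hasB, np.log(E), 0.0)
        b0neg = (~hasB) & (U < 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_b0 = -np.log(np.clip(lam[..., None] * (-U) / np.where(D > _TINY, D, 1.0), _TINY, None))
        p = np.where(b0neg, p_b0, p)
        val = np.maximum(np.sum(p * U, axis=-1), 0.0)
        val[dead] = np.inf
        out[feasible] = val
        return out


class AdditiveNoiseHamiltonian:
    """Extrinsic-noise Hamiltonian H(x,p) = p·b(x) + |p|²/2.

    ``drift_fn`` evaluates b(x) vectorized over leading axes.  The
    geometric Lagrangian is the classical ℓ(x,û) = |b(x)| − û·b(x); for a
    gradient drift b = −∇U the minimizing (uphill) path integrates to 2U.
    """

    kind = "extrinsic_additive"

    def __init__(self, drift_fn: Callable[[np.ndarray], np.ndarray], dim: int):
        self._drift = drift_fn
        self.dim = dim

    def drift(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self._drift(np.asarray(x, dtype=float)), float)

    def hamiltonian(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, float)
        return np.sum(p * self.drift(x), axis=-1) + 0.5 * np.sum(p * p, axis=-1)

    def dH_dp(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        return self.drift(x) + np.asarray(p, float)

    def geometric_lagrangian(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        U = np.atleast_2d(np.asarray(u, dtype=float))
        x, U = np.broadcast_arrays(x, U)
        b = self.drift(x)
        return np.linalg.norm(b, axis=-1) - np.sum(U * b, axis=-1)


def plane_restricted(
    H: HamiltonianSpec, fixed: dict[int, float]
) -> "_PlaneRestricted":
    """View of a Hamiltonian on an axis-aligned plane.

    Motion is restricted to the free coordinates while the momentum of the
    fixed coordinates remains free, so the cost of holding the fixed
    species at the plane value is charged (jump case) or optimized out
    (additive case).  Used for in-plane slice landscapes.
    """
    return _PlaneRestricted(H, fixed)


class _PlaneRestricted:
    def __init__(self, H: HamiltonianSpec, fixed: dict[int, float]):
        self.base = H
        self.fixed = dict(fixed)
        self.free = [k for k in range(H.dim) if k not in fixed]
        self.dim = len(self.free)
        self.kind = getattr(H, "kind", "unknown")

    def _embed(self, x2: np.ndarray) -> np.ndarray:
        x2 = np.atleast_2d(np.asarray(x2, float))
        full = np.zeros(x2.shape[:-1] + (self.base.dim,))
        for j, k in enumerate(self.free):
            full[..., k] = x2[..., j]
        for k, v in self.fixed.items():
            full[..., k] = v
        return full

    def _embed_u(self, u2: np.ndarray) -> np.ndarray:
        u2 = np.atleast_2d(np.asarray(u2, float))
        full = np.zeros(u2.shape[:-1] + (self.base.dim,))
        for j, k in enumerate(self.free):
            full[..., k] = u2[..., j]
        return full

    def drift(self, x: np.ndarray) -> np.ndarray:
        return self.base.drift(self._embed(x))[..., self.free]

    def hamiltonian(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        # in-plane momentum; the fixed coordinates carry zero momentum
        return self.base.hamiltonian(self._embed(x), self._embed_u(p))

    def dH_dp(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        return self.base.dH_dp(self._embed(x), self._embed_u(p))[..., self.free]

    def geometric_lagrangian(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        return self.base.geometric_lagrangian(self._embed(x), self._embed_u(u))
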