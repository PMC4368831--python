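# Methods

## Model and assumptions

The deterministic core is a three-variable reduction of the budding
yeast cell-cycle network: G1/S (x), early M (y) and late M/G1
inhibitors (z), each module carrying a second-order Hill positive
feedback, first-order degradation, a bilinear repression from its
successor and a linear trigger from its predecessor; a0 is basal,
nutrient-dependent production of x.  The reduction assumes a "domino"
cycle — once Start is passed the phases fire in sequence — with no cell
mass variable and no G2 phase.  All quantities are in dimensionless
concentration and time units.

Baseline parameters: j1 = j2 = j3 = 0.5, k1 = k2 = k3 = 0.2, ki = 5.0,
ks = 1.0, ka1 = ka2 = 0.001, a0 = 0.001.  Scenario presets change
exactly one parameter each: a0 → 0.01 (rich nutrient), ka1 → 0.0001
(DNA-replication checkpoint), ka2 → 0.0001 (M checkpoint).

At baseline the relevant structures are the stable G1 state
P1 ≈ (0.0056, 1.2·10⁻⁶, 4.3248) — the z-coordinate is the larger root
of (k3 + ki·x*)z² − ks·z + (k3 + ki·x*)j3² = 0, noticeably below the
uncoupled-subsystem root 4.95 because of the ki·z·x coupling — the
Start saddle P2 ≈ (0.045, 0, 2.25), and the slow-passage vertices
P3 = (x_max, 0, 0), P4 = (0, y_max, 0) with x_max ≈ 4.34, y_max ≈ 4.35
taken as the extrema of the excited trajectory (not subsystem roots:
the trigger couplings shift the vertices by ~0.6 and the stochastic
dwell localizes at the trajectory extrema).  The model also possesses a
third, biologically silent attractor near (a0/k1, ~0, ~0) (the z
feedback is bistable at x*); it is reported honestly by the fixed-point
search and participates in multi-attractor gluing but plays no role in
the cycle.

The excitable→limit-cycle bifurcation in a0 sits at a0* ≈ 0.00251
(bisection on the existence of a stable G1-like state, defined as a
stable fixed point with z > 1 and x, y < 0.5); to leading order it is
the fold of the x-subsystem with its Hill term linearized at small x,
x²/j1² − k1·x + a0, giving a0* ≈ k1²·j1²/4 = 0.0025 exactly at the
baseline constants.

## Noise models and Hamiltonians

Intrinsic noise: every additive term of the rate equations becomes one
reaction channel at system size V (12 channels; births ν = +e_k, deaths
ν = −e_k), with count-scale propensities of the printed forms (Hill:
V·X²/((jV)²+X²); linear: c·X; bilinear: X·Y/V; constant: c·V).  The
concentration-scale propensities are exactly the ODE terms, so the
mean-field identity Σ νⱼ aⱼ(Vx)/V ≡ b(x) holds for every V — an
algebraic invariant the tests assert at machine precision.  The
large-deviation Hamiltonian is H(x,p) = Σⱼ aⱼ(x)(e^{p·νⱼ} − 1); since
each channel changes one species by ±1 it separates per coordinate into
B_k(e^{p_k}−1) + D_k(e^{−p_k}−1) with aggregated birth/death rates B, D.

Extrinsic noise: ẋ = b(x) + ε·ẇ, H(x,p) = p·b(x) + |p|²/2.

## Geometric action

The time-free (Maupertuis) form of the Freidlin–Wentzell action is the
line integral of

    ℓ(x, û) = max{ p·û : H(x, p) ≤ 0 },

the support function of the convex zero-sublevel set of H in momentum.
This is the exact geometric Lagrangian: ℓ = 0 iff û is the direction of
the deterministic drift, and the maximizer is the momentum p with
∇ₚH ∥ û on {H = 0}.  For the separable jump Hamiltonian the maximizer
has a per-coordinate closed form given the Lagrange multiplier λ
(B·e^p − D·e^{−p} = λ·û_k ⇒ e^p in closed form), leaving one
safeguarded scalar bisection in λ per evaluation; coordinates with
û_k = 0 contribute −(√B_k − √D_k)², the cost rate of holding that
species still against its net flux — this term is what prices
transverse confinement and checkpoint pits correctly.  Directions with
no supporting channel (e.g. growth of a species with zero birth rate)
cost +∞.  For additive noise ℓ(x,û) = |b(x)| − û·b(x) in closed form.
Both reproduce the classical results exactly: S = 2U for gradient
drifts, and p(x) = ln(kx/c) for the 1-D birth–death process.

`geometric_action` integrates ℓ with the midpoint rule per segment;
`minimize_action` is a gMAM-style curve optimizer: L-BFGS over interior
nodes with an analytic-cost batched finite-difference gradient (moving
one node touches two segments only), alternated with equal-arc-length
reparametrization until the relative action change drops below the
tolerance (default 1e-4, at most 8 sweeps, 40 nodes).

## Lattice landscapes

`quasipotential_grid` minimizes the same geometric action over
polygonal lattice paths: nodes of a rectilinear grid are joined along a
radius-2 coprime-offset direction stencil (16 directions in 2-D, 98 in
3-D), each directed edge carries the two-point midpoint quadrature of
ℓ, and one Dijkstra sweep from the attractor cell (or from all cells of
a stored limit cycle) yields S at every node — neighbor-seeded action
minimization taken to its dynamic-programming limit.  Unreachable nodes
are NaN, never extrapolated.

Error structure: quadrature and path-resolution errors vanish with the
spacing; the fixed direction set leaves a small systematic
overestimate; structure narrower than a cell is invisible.  Two
consequences matter here.  (1) The Start barrier at baseline (the x
excursion from 0.0056 to 0.045, width ~0.04) is sub-grid on uniform
[0,6]³ grids, so the G1 well depth on such grids is understated;
path-level quantities (well depths for the sensitivity scan) use the
continuous minimizer instead.  (2) Checkpoint pit basins (spanning
0.002–0.05 in y or z) require graded axes: scenario landscapes use a
30×30×22 rectilinear grid refined near the coordinate planes and the
vertices.  Production uniform grids are 41³; tests use 21³/41³.  A 41³
landscape builds in about two minutes on one CPU, a 21³ in seconds.

The finite-difference gradient of the lattice solution is reliable on
the walls but not at the canal floor, where the V-shaped valley makes
central differences measure wall pickup (O(0.5–2.5)) although the
continuum canal is exactly flat (every canal point is reached through
the Start barrier plus zero-cost descent, and no cheaper route exists).
Canal-local gradient statements therefore use the tangential estimator
dS/ds = ℓ(x, t̂) along the integrated path (measured ~1e-10 at
baseline), and the force decomposition F = ∂H/∂p(x, ∇S) is evaluated at
the canal momentum (dS/ds)·t̂ there; on grids, F is exact wherever
∇S = 0 (∂H/∂p at p = 0 is b identically).

`hj_residual` reports |H(x, ∇S)| statistics over interior nodes with
fully defined finite-difference neighborhoods — a discretization
diagnostic (the exact S has residual zero), decreasing under
refinement.

## Global gluing

Local quasi-potentials from multiple attractors are combined by the
standard Freidlin–Wentzell construction: pairwise transition costs
V_ij = S_i(attractor_j), basin weights W_i as minimal spanning in-trees
rooted at i (exact enumeration; the model has at most three
attractors), and S_glob = min_i (W_i + S_i), normalized to zero.  For a
symmetric 1-D double well this reproduces 2U globally (tested); for a
single attractor it is the identity.  Checkpoint pits appear only in
the glued landscape: the local quasi-potential from G1 alone is flat
into the pit along the approach canal, whereas the glue lifts the
upstream canal by the pit's escape barrier.

Pit detection is plateau-robust basin depth: min(S over a shell
r..r+0.3) − min(S inside the ball of radius r = 0.5 around the vertex);
a pit is a depth exceeding 0.005 action units (lattice fluctuations on
flat regions sit well below this, the s_checkpoint pit's escape barrier
is ~0.02–0.1; the feature is the existence of the minimum, per the
model's structure, not its magnitude).

## Pseudo landscape

The global landscape is flat along the canal and therefore silent about
direction and speed.  The pseudo landscape removes the G1 well from
consideration and assigns the canal the tangential potential
T(s) = −∫₀ˢ ‖b(φ(u))‖ du along the deterministic path from P2 —
strictly decreasing, with slope equal to the driving-force strength —
while transverse structure is kept as straight-ray geometric actions in
the normal plane (near-optimal for narrow walls, an upper bound in
general).  T = −∫‖b‖ds is the minimal construction with the two
defining properties (tangential steepness ↔ force strength; transverse
shape preserved) and is isolated in one function so alternatives
(−∫‖b‖²ds, a Helmholtz-type split) can be swapped.  The pseudo
landscape is a local object; it does not represent a stationary law.

A caveat found during validation: the transverse *width* of the canal
at fixed energy offset is not uniformly narrower near P3/P4 than
mid-canal in this implementation — near the vertices the trigger
direction is weakly self-amplifying at z ≈ 0, so the straight-ray wall
there is shallow, and SSA transverse spread measurements are confounded
by projection degeneracy at the dwell knee.  The robust orderings — the
driving force is 10–100× smaller at the vertices than mid-canal, and
the extrinsic-noise width profile varies less along the path than the
intrinsic one (CoV 0.47 vs 0.51) — are asserted in tests; the width
ordering at the vertices is not.

## Stochastic simulation (the synthetic-data generator)

Exact direct-method SSA in numba kernels: exponential waiting times
from the total propensity, linear channel selection, integer state
updates; identical inputs give identical event streams, and replicate
seeds derive from one master seed via `SeedSequence`.  Three kernels:
full event recording, residence-time 3-D histogramming, and
first-passage timing.

The finite-volume landscape is −ln P̂ of the residence-normalized
histogram (the WKB scale V·S).  For the excitable baseline the global
stationary law concentrates in G1, so cycle statistics are *conditioned*
by reinjection: whenever the trajectory enters the G1 box
(x, y < 0.2, z > 2) it restarts from the point where the deterministic
excited trajectory first reaches x = 0.5, and residence within 0.5 of
P1 is not accumulated.  Defaults for the checkpoint-pit analysis:
V = 100 (small enough that the dwell-vertex rates are comparable to the
noise), 60³ bins over [0,6]³, 20 000 time units (~180 cycles, ~4·10⁶
reactions, a few seconds).  The rich-nutrient scenario needs no
reinjection.

What the generator emulates: the exact molecular-count jump process of
the 12-channel network, hence all intrinsic-noise statistics of the
model.  What it does not: extrinsic/environmental fluctuations,
parameter drift, cell growth and division asymmetry, or any molecular
detail beyond the three lumped modules — so passing tests certify the
method on this model class, not the biology of real yeast.

Exit-time analysis: mean first-passage times with bootstrap CIs;
censored replicates are reported.  The volume-scaling regression uses
ln(mean τ) − γ·ln V with γ = −1/2, the exact subexponential prefactor
of the 1-D birth–death threshold crossing (Stirling on the closed-form
MFPT sum); the measured slope bias without the correction matches
−1/(2V̄) to three digits.  The fitted slope then estimates ΔS, compared
within the t-based 95% CI of the regression.

## Numerical choices

- Integration: LSODA, rtol 1e-9/atol 1e-12 (the canal has fast–slow
  structure near P3/P4); trajectories are clipped at 0 (the orthant is
  forward-invariant up to solver tolerance).
- Fixed points: hybr root solves of the smooth (unclipped) drift from a
  Halton multi-start plus self-consistent structured guesses for the
  axis-hugging states (whose Newton basins are tiny from generic
  starts); duplicates merged at 1e-6 max-norm; stability from analytic
  Jacobian eigenvalues; records keep ‖b‖ < 1e-9.
- Bifurcation: bisection on the stable-G1 predicate, default tolerance
  1e-5 in a0.
- Limit cycles: Poincaré section at midrange x with positive crossing,
  period from the median of crossing intervals, rejected if the last
  periods vary by more than 5%.
- λ-bisection in ℓ: 64 iterations after doubling bracket expansion;
  exponent arguments clipped at ±500; infeasible directions +∞.
- Momentum/force at degenerate boundary faces: coordinates with a
  vanishing supporting rate make moves infeasible rather than cheap;
  boundary grid nodes remain valid (the cycle hugs the axes).
- Lyapunov test tolerance: grid-interpolation wiggle bound
  h · median‖∇S‖ over the grid.
- Every stochastic component takes an explicit integer seed; all seeds
  are recorded in metadata.

## Known limitations

- Lattice landscapes overestimate S slightly (fixed direction set) and
  cannot see sub-cell structure; barrier-accurate numbers should use
  `minimize_action` on the specific transition.
- The in-plane slice of a lattice landscape is a section of the 3-D
  solution; it is not recomputed with plane-restricted dynamics.
- The pseudo landscape's transverse profiles are straight-ray upper
  bounds; curved transverse minimizers would lower wide walls slightly.
- The FW gluing enumeration is exponential in the number of attractors
  (fine for ≤ 4; this model has ≤ 3).
- SSA performance relies on numba JIT; the first call in a session
  pays a compilation cost of a few seconds.
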