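"""Finite-volume landscape: -ln P from exact Gillespie simulation at V = 100.

At small system size the reaction rates near the slow vertices P3/P4 are
comparable to the noise, and the occupancy-based landscape -ln P grows
pits there that the infinite-volume quasi-potential does not have —
metastable micro-states acting as additional checkpoints.

The excitable system is reinjected into the cycle whenever it settles
back into G1, so the histogram is a conditioned (on-cycle) distribution.
"""

import numpy as np

import cyclescape as cs

params = cs.baseline_params()
V = 100.0
net = cs.build_network(params, V)

traj = cs.integrate(params, cs.excited_start(params), 60.0)
restart = np.round(traj.states[np.argmax(traj.states[:, 0] > 0.5)] * V)
p1 = next(fp for fp in cs.find_fixed_points(params, seed=0) if fp.label == "P1")

hist = cs.stationary_histogram(
    net, restart, t_total=20000.0, bins=60, seed=12345,
    restart_rule={
        "restart_state": restart,
        "g1_lo": [-1, -1, 2.0], "g1_hi": [0.2, 0.2, np.inf],
        "exclude_center": p1.location, "exclude_radius": 0.5,
    },
)
print(f"simulated {hist.meta['events']} reactions over {hist.total_weight:.0f} "
      f"time units at V = {V:.0f} (about {hist.total_weight/110:.0f} cycles)")

fv = cs.finite_volume_landscape(hist)
P = cs.passage_points(params)
d3 = cs.basin_depth(fv.slice_at(2, 0.0), (P["P3"][0], 0.0), radius=0.5)
d4 = cs.basin_depth(fv.slice_at(0, 0.0), (P["P4"][1], 0.0), radius=0.5)
print(f"-ln P pit depth near P3 (z=0 slice): {d3:.2f}")
print(f"-ln P pit depth near P4 (x=0 slice): {d4:.2f}")
print("positive depths = local minima: the slow-passage vertices hold the")
print("system in place at finite volume, unlike the flat V->infinity canal.")
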