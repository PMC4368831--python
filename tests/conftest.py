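"""Shared fixtures.

The expensive objects (3-D lattice landscapes, scenario runs) are
session-scoped so the landscape, force-field, Lyapunov and scenario
tests reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import cyclescape as cs


@pytest.fixture(scope="session")
def baseline():
    return cs.baseline_params()


@pytest.fixture(scope="session")
def baseline_fps(baseline):
    return cs.find_fixed_points(baseline, seed=0)


@pytest.fixture(scope="session")
def p1(baseline_fps):
    return next(fp for fp in baseline_fps if fp.label == "P1")


@pytest.fixture(scope="session")
def baseline_H(baseline):
    return cs.JumpHamiltonian.from_network(cs.build_network(baseline, 1.0))


def _uniform_axes(n):
    return [np.linspace(0.0, 6.0, n)] * 3


@pytest.fixture(scope="session")
def grid21(baseline_H, p1):
    return cs.quasipotential_grid(baseline_H, _uniform_axes(21), p1.location)


@pytest.fixture(scope="session")
def grid41(baseline_H, p1):
    return cs.quasipotential_grid(baseline_H, _uniform_axes(41), p1.location)


@pytest.fixture(scope="session")
def canal_path(baseline):
    from cyclescape.pseudo import reference_cycle_path

    return reference_cycle_path(baseline, n_nodes=300)


@pytest.fixture(scope="session")
def scenario_reports():
    """Full scenario runs for baseline and the S checkpoint."""
    return {
        name: cs.run_scenario(name, plan="full", seed=0)
        for name in ("baseline", "s_checkpoint")
    }


@pytest.fixture(scope="session")
def bd_network_factory():
    def make(V, birth=1.0, death=1.0):
        return cs.birth_death_network(birth, death, V)

    return make
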