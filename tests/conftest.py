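"""Shared fixtures.

Expensive artifacts (the solved policy set and the low-noise fitness table)
are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import dualproc as dp


@pytest.fixture(scope="session")
def env() -> dp.EnvironmentParams:
    return dp.EnvironmentParams()


@pytest.fixture(scope="session")
def policy_set(env) -> dp.PolicySet:
    """Default policy ladder (21 availability levels), solved once."""
    return dp.solve_policy_set(env)


@pytest.fixture(scope="session")
def fitness_table(env, policy_set) -> dp.FitnessTable:
    """Low-noise fitness surface over the access range the runs explore.

    Replicates per cell are chosen so the Monte-Carlo standard error of a
    cell (< ~0.3 energy units) is small against the fitness differences
    between adjacent control levels; a noisier table shows spurious local
    optima that stall selection.
    """
    p_levels = np.array(
        [0.0, 0.002, 0.005, 0.01, 0.02, 0.04, 0.07, 0.125, 0.25, 1.0]
    )
    n_cells = 11 * p_levels.size**2
    return dp.build_fitness_table(
        env,
        policy_set,
        p_levels=p_levels,
        n_sims=n_cells * 1200,
        steps=1000,
        seed=20_477,
    )


def tiny_synthetic_table(fn=None) -> dp.FitnessTable:
    """Small analytic fitness surface for tests that need exact control.

    Values are computed from a known closed form (default: access-weighted
    linear fitness), not from simulation; marked synthetic by construction.
    """
    c = np.linspace(0.0, 1.0, 5)
    p = np.linspace(0.0, 1.0, 4)
    C, PA, PC = np.meshgrid(c, p, p, indexing="ij")
    values = fn(C, PA, PC) if fn else 100.0 * (C * PC + (1.0 - C) * PA)
    return dp.FitnessTable(
        c_levels=c, p_auto_levels=p, p_ctrl_levels=p, values=values,
        meta={"synthetic": True},
    )
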