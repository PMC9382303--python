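"""Shared fixtures: transfer tables, settled task setups, task results.

The heavyweight objects (full-resolution transfer table, regime map, the
converged switching tasks) are session-scoped so the acceptance tests and
the unit tests share one computation.
"""

import numpy as np
import pytest

from neuroct import (ModelParameters, OptimizationSettings,
                     compute_transfer_tables)
from neuroct.control import ControlProblem, TargetSpec
from neuroct.tasks import TaskSetup, TaskSpec, run_switching_task

POINT_A = (0.45, 0.475)
POINT_B = (0.475, 0.6)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def table():
    """Full-resolution transfer table (the production default)."""
    return compute_transfer_tables()


@pytest.fixture(scope="session")
def table_coarse():
    """Half-resolution table for cheap numerical tests."""
    return compute_transfer_tables(mu_grid=np.linspace(-10, 10, 101),
                                   sigma_grid=np.linspace(0.5, 5, 21))


@pytest.fixture(scope="session")
def setup_a(params, table):
    return TaskSetup.prepare(params, table, POINT_A)


@pytest.fixture(scope="session")
def setup_b(params, table):
    return TaskSetup.prepare(params, table, POINT_B)


@pytest.fixture(scope="session")
def opt_settings():
    return OptimizationSettings(rng_seed=1, max_anneal_blocks=12,
                                anneal_period=30, cost_rtol=1e-9)


def _run_tasks(setup, point, settings):
    results = {}
    for name in ("DU1", "DU2", "UD1", "UD2"):
        task = TaskSpec.from_name(name, point)
        results[name] = run_switching_task(task, setup, settings,
                                           polish_iters=300)
    return results


@pytest.fixture(scope="session")
def task_results_a(setup_a, opt_settings):
    """All four converged switching tasks at point a."""
    return _run_tasks(setup_a, POINT_A, opt_settings)


@pytest.fixture(scope="session")
def task_results_b(setup_b, opt_settings):
    return _run_tasks(setup_b, POINT_B, opt_settings)


@pytest.fixture(scope="session")
def regime_map20(params, table):
    """20 x 20 regime map over the standard background-input window."""
    from neuroct.statespace import build_regime_map

    return build_regime_map(params, table, np.linspace(0.0, 0.8, 20),
                            np.linspace(0.0, 0.8, 20))


@pytest.fixture()
def shrunken_problem(params, table, setup_a):
    """Small DU-style problem (T = 50 ms, dt = 0.5 ms) for gradient tests."""
    target = TargetSpec(r_tilde=setup_a.up.r_E_Hz, t0=30.0, T=50.0)
    return ControlProblem(params, setup_a.background, table, setup_a.down,
                          target, dt=0.5)
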