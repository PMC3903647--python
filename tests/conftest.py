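"""Shared fixtures: the demo landscape and solved demo networks.

The heavyweight artifacts (7-species 60×60 landscape, nested networks) are
session-scoped so the design, evaluation and acceptance tests all reuse one
solve.
"""

from __future__ import annotations

import numpy as np
import pytest

from rangemon import SolverConfig, design_nested, generate_landscape
from rangemon.features import Feature, FeatureIncidence, TargetTable
from rangemon.grids import GridSpec, SuitabilityGrid
from rangemon.pipeline import prepare_problem

DEMO_SEED = 7

#: Test-scale annealing: the production schedule (1e6 iterations, 1e4
#: decreases, 100 runs) is scaled down; solution quality on the 60×60 demo
#: is unaffected because the repair pass guarantees attainable targets.
DEMO_SOLVER = dict(n_runs=5, n_iterations=50_000, n_temp_decreases=1_000)


@pytest.fixture(scope="session")
def demo_landscape():
    return generate_landscape(seed=DEMO_SEED)


@pytest.fixture(scope="session")
def demo_problem(demo_landscape):
    return prepare_problem(demo_landscape)


@pytest.fixture(scope="session")
def demo_networks(demo_problem):
    cfg = SolverConfig(seed=DEMO_SEED, **DEMO_SOLVER)
    return design_nested(demo_problem.incidence, demo_problem.statuses, cfg)


def random_instance(rng: np.random.Generator, max_units=15, max_features=6, max_target=2):
    """Small random set-cover instance for solver/oracle tests."""
    n_u = int(rng.integers(4, max_units + 1))
    n_f = int(rng.integers(2, max_features + 1))
    m = rng.random((n_u, n_f)) < 0.3
    feats = [Feature(f"s{j}", "G", "A2a") for j in range(n_f)]
    inc = FeatureIncidence(units=np.arange(n_u), features=feats, incidence=m)
    targets = {f.name: int(t) for f, t in zip(feats, rng.integers(1, max_target + 1, n_f))}
    return inc, TargetTable(targets)


def uniform_grid(n_rows=20, n_cols=20, value=0.5) -> SuitabilityGrid:
    spec = GridSpec(n_rows, n_cols)
    return SuitabilityGrid(
        values=np.full(spec.shape, value),
        valid_mask=np.ones(spec.shape, bool),
        grid=spec,
    )
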