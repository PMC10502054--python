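"""Shared fixtures.

The two reduced adhesion sweeps (the desk-scale protocol: 4 grid values
per axis, 100 initial cells, 2e5 steps) are expensive (~2 and ~7 minutes)
and are therefore session-scoped and computed lazily, so only the
acceptance tests pay for them.
"""

import numpy as np
import pytest

from celltopo.pipeline import (REDUCED_CONSTANT_GRID,
                               REDUCED_PROLIFERATION_GRID, ground_truth_labels,
                               reduced_config, run_sweep, sweep_triples)

ACCEPTANCE_SEED = 1


@pytest.fixture(scope="session")
def constant_sweep():
    triples = sweep_triples(REDUCED_CONSTANT_GRID)
    clouds = run_sweep(triples, reduced_config(False), seed=ACCEPTANCE_SEED)
    return triples, clouds, ground_truth_labels(triples, False)


@pytest.fixture(scope="session")
def proliferation_sweep():
    triples = sweep_triples(REDUCED_PROLIFERATION_GRID)
    clouds = run_sweep(triples, reduced_config(True), seed=ACCEPTANCE_SEED + 1)
    return triples, clouds, ground_truth_labels(triples, True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
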