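import numpy as np
import pandas as pd
import pytest

from mpalkit import synthetic


@pytest.fixture(scope="session")
def small_pool():
    """A small multiplexed pool with doublets and missing calls."""
    cfg = synthetic.PoolSimConfig(cells_per_patient=150, seed=7)
    return cfg, synthetic.simulate_pool(cfg)


@pytest.fixture(scope="session")
def chain_patient():
    """A patient on a 4-mutation chain with a planted CD34 shift on the tip."""
    cfg = synthetic.CloneSimConfig(
        tree_edges=(("root", "A"), ("A", "B"), ("B", "C"), ("C", "D")),
        clone_fractions=(
            ("root", 0.2), ("A", 0.2), ("B", 0.2), ("C", 0.2), ("D", 0.2),
        ),
        protein_shift_map=(("D", (("CD34", 2.0),)),),
        n_cells=300,
        seed=11,
    )
    return cfg, synthetic.simulate_clonal_patient(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced expression cohort for unit tests."""
    cfg = synthetic.ExpressionSimConfig(
        n_samples=12, cells_per_sample=60, n_genes=300, seed=5
    )
    return cfg, synthetic.simulate_expression_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
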