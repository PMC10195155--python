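import numpy as np
import pytest

import exprate as xr


@pytest.fixture(scope="session")
def study_tree():
    """Default 5-tip ultrametric study tree (depth 3)."""
    return xr.default_study_tree()


@pytest.fixture(scope="session")
def three_tip_tree():
    return xr.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_grid():
    """Coarse 12-bin grid for exhaustive-enumeration oracles."""
    return xr.Grid(0.0, 5.0, 12)


@pytest.fixture(scope="session")
def sim_dataset(study_tree):
    """A moderate simulated dataset (sigma^2 = 1) reused across tests."""
    config = xr.SimConfig(
        tree=study_tree, rates=xr.RateModel.single(1.0), n_genes=500, seed=2024
    )
    return xr.simulate(config)


def make_table(species, values, missing=None, samples=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    g = values.shape[0]
    if missing is None:
        missing = np.zeros_like(values, dtype=bool)
    return xr.ExpressionTable(
        gene_ids=gene_ids or [f"g{i + 1}" for i in range(g)],
        samples=samples or ["default"] * g,
        descriptions=[""] * g,
        species=list(species),
        values=np.where(np.asarray(missing, bool), np.nan, values),
        missing=np.asarray(missing, bool),
    )


@pytest.fixture
def table_factory():
    return make_table
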