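import numpy as np
import pandas as pd
import pytest

from regulonpipe.datatypes import ActivityMatrix, ExpressionMatrix, Regulon, SurvivalCohort
from regulonpipe.synthetic import SimConfig, simulate_bulk_cohort, simulate_single_cell


def small_config(**kw) -> SimConfig:
    """A fast single-cell config used across unit tests."""
    defaults = dict(
        n_cells=200,
        n_genes=800,
        n_tfs=12,
        targets_per_regulon=10,
        n_modules=3,
        seed=7,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    cfg = small_config()
    matrix, truth = simulate_single_cell(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_samples=120, seed=11)
    cohort, truth = simulate_bulk_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture()
def tiny_matrix():
    """3 genes x 2 cells with hand-set values."""
    values = pd.DataFrame(
        [[5.0, 0.0], [1.0, 2.0], [0.0, 3.0]],
        index=["G1", "G2", "G3"],
        columns=["c1", "c2"],
    )
    return ExpressionMatrix(values)


@pytest.fixture()
def toy_activity():
    """8 regulons x 40 cells of random RAS with fixed seed."""
    rng = np.random.default_rng(3)
    values = pd.DataFrame(
        rng.random((8, 40)),
        index=[f"R{i}" for i in range(8)],
        columns=[f"c{i}" for i in range(40)],
    )
    meta = pd.DataFrame({"condition": ["WT"] * 20 + ["MUT"] * 20}, index=values.columns)
    return ActivityMatrix(values, meta)


@pytest.fixture()
def toy_survival():
    """Five samples, one censored, with hand-checkable times."""
    samples = [f"s{i}" for i in range(5)]
    expr = pd.DataFrame({"g1": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=samples)
    return SurvivalCohort(
        expression=expr,
        time=pd.Series([2.0, 4.0, 6.0, 8.0, 10.0], index=samples),
        event=pd.Series([1, 1, 0, 1, 1], index=samples),
        name="toy",
    )
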