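import numpy as np
import pandas as pd
import pytest

from carmap import AdjacencyGraph, StratifiedAreaTable
from carmap.standardization import STRATA


@pytest.fixture
def path3():
    """Three areas in a line: a - b - c."""
    return AdjacencyGraph.from_edge_list(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def lattice33():
    return AdjacencyGraph.lattice(3, 3)


@pytest.fixture
def cycle4():
    return AdjacencyGraph.from_edge_list(
        ["a", "b", "c", "d"], [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


def random_table(rng: np.random.Generator, n_areas: int) -> StratifiedAreaTable:
    """A random stratified table with positive person-years in every stratum."""
    rows = []
    for i in range(n_areas):
        for sex, ag in STRATA:
            py = float(rng.uniform(50, 5000))
            rows.append({"area_id": f"A{i:04d}", "sex": sex, "age_group": ag,
                         "person_years": py,
                         "cases": int(rng.poisson(py * 2e-4))})
    return StratifiedAreaTable(pd.DataFrame(rows))


@pytest.fixture
def table_rng():
    return np.random.default_rng(12345)
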