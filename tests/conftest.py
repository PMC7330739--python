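import numpy as np
import pandas as pd
import pytest

from eagl.cohort import CohortTable
from eagl.spectral import Graph


@pytest.fixture
def path3():
    return Graph(["a", "b", "c"], [(0, 1), (1, 2)], directed=False)


@pytest.fixture
def triangle():
    return Graph(["a", "b", "c"], [(0, 1), (0, 2), (1, 2)], directed=False)


@pytest.fixture
def cycle4():
    return Graph(list("abcd"), [(0, 1), (1, 2), (2, 3), (0, 3)], directed=False)


def make_cohort(columns: dict[str, list[int]]) -> CohortTable:
    """Cohort from explicit column lists; keys must be <COND>_Y<k> labels."""
    return CohortTable(pd.DataFrame(columns))


@pytest.fixture
def tiny_cohort():
    # two conditions, two years, 8 patients; B_Y2 mostly copies A_Y1
    return make_cohort(
        {
            "A_Y1": [0, 0, 1, 1, 0, 1, 1, 0],
            "B_Y1": [0, 1, 0, 1, 1, 0, 0, 1],
            "A_Y2": [0, 0, 1, 1, 0, 1, 0, 0],
            "B_Y2": [0, 0, 1, 1, 0, 1, 1, 1],
        }
    )


def random_undirected_graph(rng: np.random.Generator, n: int, p: float) -> Graph:
    g = Graph([f"n{i}" for i in range(n)], directed=False)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g
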