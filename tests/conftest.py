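import dataclasses

import numpy as np
import pytest

import richclub as rc


def toy_matrix(edges: dict[tuple[int, int], float], n: int) -> rc.ConnectomeMatrix:
    w = np.zeros((n, n))
    for (i, j), v in edges.items():
        w[i, j] = w[j, i] = v
    return rc.ConnectomeMatrix(w)


@pytest.fixture
def chain5():
    """5-node network: ab=5, ac=4, bc=3, cd=2, de=1 (degrees 2,2,3,2,1)."""
    return toy_matrix({(0, 1): 5, (0, 2): 4, (1, 2): 3, (2, 3): 2, (3, 4): 1}, 5)


@pytest.fixture
def complete68():
    w = np.ones((68, 68))
    np.fill_diagonal(w, 0)
    return rc.ConnectomeMatrix(w)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (37 controls / 20 bvFTD / 23 EOAD)."""
    cohort, truth = rc.generate_cohort(rc.default_spec(seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no lesions: groups exchangeable by construction."""
    spec = rc.GeneratorSpec(seed=17)
    cohort, truth = rc.generate_cohort(spec)
    return cohort, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Quick cohort for plumbing tests (8/6/6 subjects)."""
    spec = dataclasses.replace(
        rc.default_spec(n_per_group={"control": 8, "bvFTD": 6, "EOAD": 6}), seed=23
    )
    cohort, truth = rc.generate_cohort(spec)
    return cohort, truth
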