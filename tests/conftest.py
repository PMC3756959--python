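import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def region_table():
    from swallownet.atlas import load_region_table

    return load_region_table()


@pytest.fixture(scope="session")
def small_cohort():
    """Four short subjects on 12 regions, enough to drive every stage."""
    from swallownet.synthetic import CohortSpec, generate_cohort

    spec = CohortSpec(n_subjects=4, n_volumes=120, n_regions=12,
                      local_block_size=3, seed=7)
    return spec, generate_cohort(spec)


def random_graph(rng: np.random.Generator, n: int, weighted: bool, p: float = 0.5):
    """Random symmetric adjacency with zero diagonal; weights in (0, 1]."""
    mask = np.triu(rng.random((n, n)) < p, k=1)
    if weighted:
        vals = rng.uniform(0.1, 1.0, size=(n, n))
        adj = np.where(mask, vals, 0.0)
    else:
        adj = mask.astype(float)
    return adj + adj.T
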