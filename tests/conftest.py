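import numpy as np
import pytest

from fdnet.atlas import load_default_atlas
from fdnet.network import FdCohortTable, N_ROI


@pytest.fixture(scope="session")
def atlas():
    return load_default_atlas()


def random_symmetric(n: int, rng: np.random.Generator, density: float = 0.5) -> np.ndarray:
    """Random non-negative symmetric weighted adjacency with zero diagonal."""
    w = rng.random((n, n))
    w[rng.random((n, n)) > density] = 0.0
    w = np.triu(w, k=1)
    return w + w.T


def cohort_from_fd(fd: np.ndarray, groups=None, sexes=None) -> FdCohortTable:
    """Wrap an (n × 68) FD matrix into a cohort table with default labels."""
    n = fd.shape[0]
    if groups is None:
        groups = ["A"] * n
    if sexes is None:
        sexes = (["F", "M"] * ((n + 1) // 2))[:n]
    return FdCohortTable(
        subject_ids=[f"s{i:03d}" for i in range(n)],
        group=np.array(groups, dtype=object),
        sex=np.array(sexes, dtype=object),
        fd=fd,
    )


@pytest.fixture
def small_cohort():
    """12 subjects × 68 ROIs of mild noise around 2.2, two groups, balanced sex."""
    rng = np.random.default_rng(42)
    fd = 2.2 + 0.05 * rng.standard_normal((12, N_ROI))
    return cohort_from_fd(fd, groups=["A"] * 6 + ["B"] * 6,
                          sexes=["F", "M"] * 6)
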