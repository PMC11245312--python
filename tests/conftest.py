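import numpy as np
import pytest

from statemix import BulkMatrix, ReferenceProfile, fixture_small


@pytest.fixture
def two_state_ref() -> ReferenceProfile:
    """Two genes, two states mapping to two types; exactly identifiable."""
    return ReferenceProfile(
        A=np.array([[0.8, 0.2], [0.2, 0.8]]),
        gene_ids=["g1", "g2"],
        state_ids=["s1", "s2"],
        state_to_type={"s1": "k1", "s2": "k2"},
        type_ids=["k1", "k2"],
    )


@pytest.fixture
def two_gene_bulk() -> BulkMatrix:
    """Bulk column (60, 40): exact fit of the two-state reference at (2/3, 1/3)."""
    return BulkMatrix(
        X=np.array([[60.0], [40.0]]), gene_ids=["g1", "g2"], sample_ids=["b1"]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic 50-gene / 3-type / 6-state synthetic dataset."""
    return fixture_small(seed=0)


def simplex_grid(n_states: int, step: float = 0.01) -> np.ndarray:
    """All fraction vectors on the simplex with coordinates in steps of `step`."""
    n = round(1.0 / step)
    if n_states == 2:
        a = np.arange(n + 1)
        grid = np.column_stack([a, n - a])
    elif n_states == 3:
        pts = []
        for i in range(n + 1):
            for j in range(n + 1 - i):
                pts.append((i, j, n - i - j))
        grid = np.array(pts)
    else:
        raise ValueError("grid oracle supports 2 or 3 states")
    return grid / n


def grid_search_mle(x: np.ndarray, A: np.ndarray, step: float = 0.01) -> np.ndarray:
    """Brute-force multinomial MLE over a simplex grid (independent oracle)."""
    grid = simplex_grid(A.shape[1], step)
    mix = A @ grid.T  # gene × points
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(x[:, None] > 0, x[:, None] * np.log(mix), 0.0).sum(axis=0)
    ll[np.isnan(ll)] = -np.inf
    return grid[np.argmax(ll)]
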