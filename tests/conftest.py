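import numpy as np
import pytest

from scalestep import GeneratorConfig, ResponseMatrix, generate_grm


def guttman_matrix(n_items: int = 5, reps: int = 3, interior_only: bool = False):
    """Perfect Guttman (deterministic cumulative) dichotomous data."""
    patterns = np.tril(np.ones((n_items + 1, n_items), dtype=int), -1)
    if interior_only:
        patterns = patterns[1:-1]
    values = patterns[np.repeat(np.arange(len(patterns)), reps)]
    return ResponseMatrix(
        values=values,
        missing_mask=np.zeros_like(values, dtype=bool),
        item_ids=[f"i{k}" for k in range(n_items)],
        n_categories=np.full(n_items, 2),
    )


@pytest.fixture
def guttman():
    return guttman_matrix()


@pytest.fixture
def small_pair():
    """The 4-person 2-item matrix with a perfect positive pair."""
    values = np.array([[0, 0], [0, 1], [1, 1], [1, 1]])
    return ResponseMatrix(
        values=values,
        missing_mask=np.zeros_like(values, dtype=bool),
        item_ids=["x1", "x2"],
        n_categories=np.array([2, 2]),
    )


@pytest.fixture(scope="session")
def grm_data_1000():
    """A moderately sized unidimensional graded-response dataset with truth."""
    cfg = GeneratorConfig(
        n_persons=1000,
        a=np.linspace(0.5, 2.5, 9),
        b=np.linspace(-1.0, 1.5, 9),
        t=np.array([-1.05, -0.35, 0.35, 1.05]),
        seed=7,
    )
    return generate_grm(cfg)


def make_matrix(values, n_categories=None, mask=None):
    values = np.asarray(values, dtype=int)
    if n_categories is None:
        n_categories = values.max(axis=0) + 1
        n_categories = np.maximum(n_categories, 2)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    return ResponseMatrix(
        values=values,
        missing_mask=mask,
        item_ids=[f"i{k}" for k in range(values.shape[1])],
        n_categories=np.asarray(n_categories, dtype=int),
    )
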