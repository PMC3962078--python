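import numpy as np
import pytest

from rdcvpls import DescriptorTable
from rdcvpls.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """20 objects x 6 descriptors, 2 informative, mild noise."""
    table, truth = generate(
        SyntheticSpec(
            n=20,
            blocks=((2, 0.6),),
            m_noise=4,
            support=((0, 2.0), (3, -1.0)),
            noise_sd=0.3,
            seed=99,
        )
    )
    return table, truth


@pytest.fixture
def handmade_table():
    """A tiny table written out by hand for exact-value checks."""
    X = np.array([[0.0, 1.0], [1.0, 3.0], [2.0, 5.0], [3.0, 7.0]])
    return DescriptorTable(
        X=X,
        variable_names=["d1", "d2"],
        object_names=["o1", "o2", "o3", "o4"],
        y=np.array([1.0, 2.0, 3.0, 4.0]),
    )


def ols_predictions(X, y):
    """Independent oracle: OLS fit with intercept via normal equations."""
    design = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    return design @ beta
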