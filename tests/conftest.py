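import numpy as np
import pytest

from lianaspec._grid import default_grid
from lianaspec.canopy import SoilModel, ViewGeometry
from lianaspec.coefficients import default_table
from lianaspec.leaf import LeafParams
from lianaspec.synthetic import DEFAULT_TRAITS, trait_means


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def table10(table):
    return table.subset(default_grid(10))


@pytest.fixture(scope="session")
def wl10():
    return default_grid(10)


@pytest.fixture(scope="session")
def soil10(wl10):
    return SoilModel.default(wl10)


@pytest.fixture(scope="session")
def geom():
    return ViewGeometry(30.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def liana_leaf():
    return LeafParams.from_dict(trait_means(DEFAULT_TRAITS["liana"]))


@pytest.fixture(scope="session")
def tree_leaf():
    return LeafParams.from_dict(trait_means(DEFAULT_TRAITS["tree"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_leaf_params(rng, n):
    """Random physically valid leaf parameter draws."""
    out = []
    for _ in range(n):
        out.append(
            LeafParams(
                n_layers=rng.uniform(1.0, 3.5),
                c_ab=rng.uniform(0.0, 100.0),
                c_ar=rng.uniform(0.0, 30.0),
                c_an=rng.uniform(0.0, 10.0),
                c_br=rng.uniform(0.0, 1.0),
                c_w=rng.uniform(0.0, 0.05),
                c_m=rng.uniform(0.0, 0.03),
            )
        )
    return out
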