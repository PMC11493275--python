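import numpy as np
import pytest

from crownagb.core import TreeRecord
from crownagb import synthetic_forest as sf


@pytest.fixture(scope="session")
def default_trees():
    """Default four-plot synthetic population (seed 0)."""
    return sf.sample_tree_population(sf.default_forest_config(seed=0))


@pytest.fixture(scope="session")
def grid_stand():
    """16 conifers on an 8 m grid — well separated, known attributes."""
    rng = np.random.default_rng(7)
    trees = []
    i = 0
    for gx in range(4):
        for gy in range(4):
            trees.append(TreeRecord(
                tree_id=i, plot_id=1, species="larch",
                x=6.0 + gx * 8.0, y=6.0 + gy * 8.0,
                H=float(rng.uniform(10, 15)), DBH=float(rng.uniform(14, 19)),
                R=float(rng.uniform(1.8, 3.0))))
            i += 1
    return trees


@pytest.fixture(scope="session")
def grid_stand_cloud(grid_stand):
    return sf.render_point_cloud(grid_stand, mode="ALS", density=40,
                                 extent=(0, 0, 36, 36), seed=3)
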