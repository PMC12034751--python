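import numpy as np
import pytest

from canopyfractal.cloud import PointCloud
from canopyfractal.synthetic import TreeSpec, generate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_cube_corners():
    """The 8 corners of the unit cube as a PointCloud."""
    g = np.array([0.0, 1.0])
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    return PointCloud(np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]))


@pytest.fixture(scope="session")
def conifer_tree():
    """A mid-sized needle-leaved tree with known ground truth."""
    spec = TreeSpec(
        species_label="Pinus",
        form="conifer",
        tth=15.0,
        cbh=6.0,
        crown_radius=2.2,
        stem_dbh_cm=[30.0],
        crown_fill=0.7,
        branch_density=1.0,
        rng_seed=5,
    )
    return spec, generate_tree(spec).cloud


@pytest.fixture(scope="session")
def broadleaf_tree():
    """A mid-sized broad-leaved tree with known ground truth."""
    spec = TreeSpec(
        species_label="Alnus",
        form="broadleaf",
        tth=15.0,
        cbh=6.0,
        crown_radius=3.0,
        stem_dbh_cm=[30.0],
        crown_fill=0.7,
        branch_density=1.0,
        rng_seed=5,
    )
    return spec, generate_tree(spec).cloud
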