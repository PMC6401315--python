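import numpy as np
import pytest

from uavqtl import synthfield as sf
from uavqtl.raster import Affine, Raster


@pytest.fixture(scope="session")
def small_design():
    """36-line field (18 TEM + 18 TST), 6 plots per row: fast to rasterize."""
    groups = tuple(["TEM"] * 18 + ["TST"] * 18)
    return sf.FieldDesign(groups=groups, n_cols=6)


@pytest.fixture(scope="session")
def small_truth(small_design):
    return sf.generate_true_heights(small_design, sf.GrowthParams(), seed=202)


@pytest.fixture(scope="session")
def panel_truth():
    """True heights for the default 252-line panel (117 TEM + 135 TST)."""
    design = sf.FieldDesign()
    return sf.generate_true_heights(design, sf.GrowthParams(), seed=77)


@pytest.fixture(scope="session")
def small_terrain(small_design):
    return sf.generate_terrain(small_design, relief_amplitude=10.0, seed=201)


@pytest.fixture(scope="session")
def small_plots(small_design):
    return small_design.plot_map()


def flat_raster(value=0.0, shape=(10, 10), pixel=1.0):
    return Raster(np.full(shape, float(value)), Affine.north_up(0.0, shape[0] * pixel, pixel))
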