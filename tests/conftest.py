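import numpy as np
import pytest

import noiselur as nl


@pytest.fixture(scope="session")
def scene150():
    """A mid-size synthetic study area shared across the suite."""
    return nl.generate_scene(seed=7, n_rows=150, n_cols=150)


@pytest.fixture(scope="session")
def lden150(scene150):
    """Acoustic-fixture reference Lden for the shared scene."""
    return nl.simulate_lden(scene150, nl.AcousticParams())


@pytest.fixture(scope="session")
def stack150(scene150):
    """Full 126-column candidate predictor stack for the shared scene."""
    return nl.build_feature_stack(scene150)


@pytest.fixture()
def flat_grid():
    """A tiny all-zero 10-m grid with top-left origin at (0, 100)."""
    return nl.RasterGrid(np.zeros((10, 10)), origin_x=0.0, origin_y=100.0,
                         cell_size=10.0)
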