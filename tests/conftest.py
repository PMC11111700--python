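import numpy as np
import pandas as pd
import pytest

import vigapfill as vg


def make_cube(values, start="2001-01-01", grid=None):
    """Build a DailyVICube from a (time, lat, lon) or (time,) array."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None, None]
    grid = grid or vg.GridSpec.toy(values.shape[1], values.shape[2])
    times = pd.date_range(start, periods=values.shape[0], freq="D")
    return vg.DailyVICube(grid, times, values)


@pytest.fixture
def toy_grid():
    return vg.GridSpec.toy(4, 4)


@pytest.fixture(scope="session")
def standard_scene():
    """The seeded 20x20 x 3-year contaminated scene used across tests."""
    return vg.default_scene(20, 20, range(2001, 2004), seed=42)


@pytest.fixture(scope="session")
def standard_pipeline(standard_scene):
    """Scene -> mask -> gap-free reconstruction, computed once per session."""
    mask = vg.identify_valid(standard_scene.observed)
    recon, report = vg.reconstruct_cube(standard_scene.observed, mask)
    return standard_scene, mask, recon, report
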