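import numpy as np
import pytest

import sptmix as sx


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_movie():
    """One modest simulated movie with ground truth, shared across tests."""
    acq = sx.AcquisitionConfig(n_frames=2000)
    geo = sx.CellGeometry(n_cells=60)
    locs, truth = sx.simulate_movie(acq, sx.CONTROL_SPECIES, geo, rng=3)
    return acq, geo, locs, truth
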