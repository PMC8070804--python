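import numpy as np
import pytest

from omiflim import flim_fit as ff
from omiflim import synthetic_data as sd


@pytest.fixture(scope="session")
def irf():
    """Default synthetic Gaussian IRF on the default time grid."""
    return sd.default_irf()


@pytest.fixture(scope="session")
def small_irf():
    """Short delta-kernel grid for cheap model-level tests."""
    return ff.InstrumentResponse.delta(n_bins=64, bin_width_ns=0.05)


@pytest.fixture(scope="session")
def cohort_table():
    """One table-level synthetic cohort, shared across tests."""
    return sd.cohort(seed=11)


@pytest.fixture(scope="session")
def scene():
    """One rendered two-channel FLIM scene with ground truth."""
    preset = sd.ScenePreset()
    nadh, fad, masks, truth = sd.render_scene(preset, seed=7)
    return {"preset": preset, "nadh": nadh, "fad": fad,
            "masks": masks, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
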