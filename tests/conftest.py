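import numpy as np
import pytest

import sarcotrem as st


@pytest.fixture(scope="session")
def wt_reference():
    """Scored panel of wild-type-like reference fields (shared: expensive)."""
    return st.reference_scores()


@pytest.fixture(scope="session")
def clean_grating():
    """Noiseless 2.5 um Z-disk grating, 25.6 x 25.6 um field."""
    truth = st.ImageGroundTruth(period_um=2.5, pixel_size_um=0.1, seed=0)
    return st.generate_striated_image(truth, 256, 256)


@pytest.fixture(scope="session")
def clean_doublet():
    """Noiseless C-zone doublet image (2.5 um period, 0.9 um gap)."""
    truth = st.ImageGroundTruth(
        pattern="czone_doublet",
        period_um=2.5,
        doublet_gap_um=0.9,
        pixel_size_um=0.1,
        seed=0,
    )
    return st.generate_striated_image(truth, 256, 256)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
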