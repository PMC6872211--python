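import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rgcsample as r
from rgcsample import classification, synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: marker-identified types used to calibrate thresholds in tests
CALIBRATION_TYPES = ("1wt", "4ow", "6sw", "8w", "37c", "37d", "2an", "63", "6t")


@pytest.fixture(scope="session")
def library():
    return r.default_library()


@pytest.fixture(scope="session")
def thresholds(library):
    rng = np.random.default_rng(42)
    identified = []
    for name in CALIBRATION_TYPES:
        for _ in range(4):
            identified.append((synthetic.profile_draw(library, name, 0.1, rng), name))
    return classification.calibrate_thresholds(identified, library)


@pytest.fixture(scope="session")
def discriminators(library):
    return classification.fit_pair_discriminators(library)


@pytest.fixture(scope="session")
def bands():
    """Curved noiseless band surfaces with a dense annotation."""
    return synthetic.generate_chat_bands(
        x_extent=300, y_extent=300, curvature_amp=10.0, band_gap=12.0,
        noise_sd=0.0, n_points=400, seed=3,
    )


@pytest.fixture(scope="session")
def fitted_surfaces(bands):
    from rgcsample import chat_surface

    on, off = chat_surface.fit_annotation(bands.annotation, smoothness=0.1)
    return on, off
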