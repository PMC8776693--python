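import numpy as np
import pytest

from ofrad.cohort import CohortConfig, sample_clinical_table
from ofrad.image import ImageVolume, ROIMask


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        n_patients=24,
        seed=7,
        image_shape=(32, 32, 32),
        volume_range_ml=(3.0, 60.0),
        texture_effect_size=1.5,
    )


@pytest.fixture(scope="session")
def small_records(small_config):
    return sample_clinical_table(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def ball_pair():
    """20 mm-radius ball on a 2 mm grid with smooth but non-trivial texture."""
    shape = (28, 28, 28)
    spacing = (2.0, 2.0, 2.0)
    centre = np.array([27.0, 27.0, 27.0])
    grids = np.meshgrid(*[(np.arange(s) + 0.5) * sp for s, sp in zip(shape, spacing)], indexing="ij")
    r2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
    mask = ROIMask(r2 <= 20.0**2, spacing)
    x, y, z = grids
    values = 50.0 + 0.7 * x + 8.0 * np.sin(x / 5.0) * np.cos(y / 7.0) + 5.0 * np.sin(z / 4.0 + 1.0)
    img = ImageVolume(values, spacing)
    return img, mask
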