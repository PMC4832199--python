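import numpy as np
import pytest

from cadx import SynthConfig, generate_ct_dataset, generate_us_dataset


@pytest.fixture(scope="session")
def small_us_cases():
    cfg = SynthConfig(modality="us", n_benign=12, n_malignant=12, image_size=48, seed=11)
    return generate_us_dataset(cfg)


@pytest.fixture(scope="session")
def small_ct_cases():
    cfg = SynthConfig(
        modality="ct", n_benign=12, n_malignant=12, image_size=48,
        pixel_spacing=0.7, slice_thickness=1.5, slices_per_case_range=(2, 6), seed=12,
    )
    return generate_ct_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
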