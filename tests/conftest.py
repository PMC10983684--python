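import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_images():
    """Small balanced synthetic set (7 classes x 4 images, 48 px) for
    inference-level tests that need pixels but not a trained model."""
    from noseleaf.synthetic import SPECIES, SyntheticSpec, generate_arrays
    spec = SyntheticSpec(per_class_counts={c: 4 for c in SPECIES},
                         image_size=48, seed=11)
    return generate_arrays(spec)
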