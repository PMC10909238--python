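import numpy as np
import pytest

from dtocrop.synthetic import ClassSpec, generate_imageset


@pytest.fixture(scope="session")
def separable_imageset():
    """Two well-separated classes of small patches, shared across tests."""
    specs = [
        ClassSpec("dark", 40, np.array([0.2, 0.25, 0.3])),
        ClassSpec("bright", 40, np.array([0.7, 0.75, 0.8])),
    ]
    return generate_imageset(specs, bands=3, patch_size=16, noise_sd=0.05, seed=11)


@pytest.fixture
def sphere():
    return lambda x: float(np.sum(np.square(x)))
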