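import numpy as np
import pytest

from deepblastoid import synthgen as sg


@pytest.fixture(scope="session")
def balanced_tiles():
    """700 interference-free 64-px tiles with exactly 140 per class.

    Session-scoped: generation is deterministic, so sharing across tests
    is safe.
    """
    spec = sg.SyntheticDatasetSpec(
        n_images=700, image_size_px=64, seed=11, exact_counts=True
    )
    images, masks, codes, manifest = sg.generate_tiles(spec)
    return images, masks, codes, manifest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
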