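import numpy as np
import pytest

from rdaunet import PhantomSpec, generate_dataset
from rdaunet.ct_io import MaskSlice, SamplePair


@pytest.fixture(scope="session")
def small_phantoms():
    """Twelve 64x64 phantoms spanning the shape/lesion taxonomy."""
    return generate_dataset(12, PhantomSpec(side=64), seed=7)


@pytest.fixture(scope="session")
def organ_pairs(small_phantoms):
    return [organ for organ, _ in small_phantoms]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_pair(image, mask, slice_id="t"):
    return SamplePair(np.asarray(image, dtype=float), MaskSlice(np.asarray(mask)),
                      slice_id)
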