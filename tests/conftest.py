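import numpy as np
import pytest

from lcrep.reference import load_bundled_reference


@pytest.fixture(scope="session")
def reference():
    return load_bundled_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def kv133_kj1(reference):
    """Unmutated IGKV1-33 + IGKJ1 rearrangement."""
    return reference.get("IGKV1-33").aa_seq + reference.get("IGKJ1").aa_seq
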