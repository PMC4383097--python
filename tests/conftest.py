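import numpy as np
import pytest

from ampliquant import build_reference_window, make_example_locus
from ampliquant.simulate import DEFAULT_HDR_INSERT


@pytest.fixture(scope="session")
def example_locus():
    """Deterministic synthetic 640-nt locus with the protospacer at offset 100."""
    return make_example_locus()


@pytest.fixture(scope="session")
def example_window(example_locus):
    return build_reference_window(example_locus, flank=15, expected_insert=DEFAULT_HDR_INSERT)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
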