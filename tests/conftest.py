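import numpy as np
import pytest

from contactnet.msa_io import msa_from_strings
from contactnet.pipeline import family_to_example
from contactnet.synthetic import make_family


@pytest.fixture(scope="session")
def small_family():
    """One synthetic family at the standard desk-scale conditions."""
    rng = np.random.default_rng(7)
    return make_family(60, 100, 20, rng, coupling_strength=2.0)


@pytest.fixture(scope="session")
def small_example(small_family):
    return family_to_example(small_family)


@pytest.fixture
def toy_msa():
    return msa_from_strings(["ACDEFG", "ACDEFG", "AC-EYG", "WCDEFG", "ACDKFG"])


def random_msa(rng, n, L, gap_rate=0.1):
    codes = rng.integers(0, 20, size=(n, L))
    codes[rng.random((n, L)) < gap_rate] = 20
    codes[0, codes[0] == 20] = 0  # gapless query row
    from contactnet.msa_io import Msa

    return Msa(ids=[f"s{i}" for i in range(n)], codes=codes.astype(np.int8))
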