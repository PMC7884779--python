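import random

import pytest

from pegcraft import DesignParams, load_cfd_matrix
from pegcraft.fixtures import EDIT_TYPES, random_locus


@pytest.fixture(scope="session")
def cfd_matrix():
    return load_cfd_matrix()


@pytest.fixture(scope="session")
def default_params():
    return DesignParams()


@pytest.fixture(scope="session")
def random_loci():
    """60 seeded loci, 200-500 nt, cycling through all four edit types."""
    rng = random.Random(20240)
    return [
        random_locus(rng, rng.randrange(200, 501), EDIT_TYPES[i % 4])
        for i in range(60)
    ]
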