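import random

import pytest

from rnapal.params import default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture()
def rng():
    return random.Random(20260926)


def random_rna(rng, length: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(length))
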