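import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pistolkit.scaffold import default_scaffold
from pistolkit import synthetic


@pytest.fixture(scope="session")
def scaffold():
    return default_scaffold()


@pytest.fixture(scope="session")
def standin_target():
    """Synthetic stand-in for the PD-L1 CDS with the four screened GU sites."""
    return synthetic.standin_target(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
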