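import numpy as np
import pytest

from torsionnet.synthetic import (
    default_coupling_pairs,
    generate_dataset,
    make_branched_molecule,
    make_chain_molecule,
    make_pes,
)


@pytest.fixture(scope="session")
def chain():
    """Linear 3-torsion fixture molecule (4 rigid fragments)."""
    return make_chain_molecule(3)


@pytest.fixture(scope="session")
def branched():
    """Hub-branched 3-arm fixture (the shape where 1-D scans fail)."""
    return make_branched_molecule(3)


@pytest.fixture(scope="session")
def separable_pes():
    return make_pes(3, None, 0.0, seed=11)


@pytest.fixture(scope="session")
def coupled_pes():
    return make_pes(3, default_coupling_pairs(3, "hub"), 1.0, seed=13)


@pytest.fixture(scope="session")
def coupled_dataset(coupled_pes):
    return generate_dataset(coupled_pes, 5000, seed=14)
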