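import numpy as np
import pytest

from pepbind import structure, synthetic


@pytest.fixture(scope="session")
def toy_complex():
    """Deterministic toy two-chain complex with its ground-truth tables."""
    pdb_text, truth = synthetic.generate_toy_complex(seed=7)
    return pdb_text, truth


@pytest.fixture(scope="session")
def toy_model(toy_complex):
    pdb_text, _ = toy_complex
    return structure.parse_structure(pdb_text)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
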