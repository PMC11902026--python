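import numpy as np
import pytest

from quadbind import datasets


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture
def ribavirin_lines():
    """The 12 experimental NQR frequencies of crystalline ribavirin."""
    lines = []
    for entry in datasets.RIBAVIRIN_NQR_LINES.values():
        lines.extend(entry["triplet"])
    return lines


@pytest.fixture
def ligand_graphs():
    from quadbind import parse_structure

    return {
        name: parse_structure(smi)
        for name, smi in datasets.LIGAND_SMILES.items()
    }
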