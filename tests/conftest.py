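import numpy as np
import pytest

from snapqsar.fixtures import FixtureSpec, generate_library
from snapqsar.molecule_prep import MoleculeRecord, embed_3d


@pytest.fixture(scope="session")
def ethanol_conformer():
    return embed_3d(MoleculeRecord(id="ethanol", smiles="CCO"), seed=7)


@pytest.fixture(scope="session")
def methane_conformer():
    return embed_3d(MoleculeRecord(id="methane", smiles="C"), seed=7)


@pytest.fixture(scope="session")
def small_library():
    """Deterministic 60-molecule synthetic library, ~10% active."""
    return generate_library(
        FixtureSpec(n_molecules=60, active_fraction=0.10, seed=11))


@pytest.fixture
def library_csv(tmp_path):
    """Write a minimal well-formed molecule table and return its path."""

    def _write(rows, name="lib.csv", header="id,smiles,activity_score"):
        path = tmp_path / name
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return _write


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
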