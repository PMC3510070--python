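import numpy as np
import pytest

from allodyn import synthetic_fixtures as sf
from allodyn.structio import Ensemble, Residue, StructureModel


@pytest.fixture
def toy_pdb(tmp_path):
    """8-residue toy helix written to disk."""
    path = tmp_path / "toy.pdb"
    sf.make_toy_structure(8, "helix", seed=0, path=path)
    return path


@pytest.fixture
def toy_ensemble():
    return sf.make_toy_structure(8, "helix", seed=0)


@pytest.fixture
def ensemble5_pdb(tmp_path):
    """5-model ensemble file with mild uniform flexibility."""
    path = tmp_path / "ens5.pdb"
    sf.make_flex_ensemble(6, 5, np.full(6, 0.2), seed=1, path=path)
    return path


def poly_ala(n: int) -> Ensemble:
    """A poly-alanine chain (every residue has a single-symbol alphabet)."""
    residues = []
    for i in range(n):
        ca = np.array([3.8 * i, 0.0, 0.0])
        residues.append(Residue(i + 1, "A", {
            "N": ca + [-1.0, 0.9, 0.0],
            "CA": ca,
            "C": ca + [1.0, 0.9, 0.0],
            "CB": ca + [0.0, -1.4, 0.6],
        }))
    return Ensemble([StructureModel(0, residues)])
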