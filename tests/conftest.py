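import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sugarstack.structure_model import AtomSite, StructureModel


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation in [-20, 20]³."""
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


def hexagon_ring_model(radius: float = 1.39, residue: str = "TYR",
                       chain: str = "A", seq: int = 1) -> StructureModel:
    """A TYR/PHE-style regular hexagon in the z = 0 plane centered at origin."""
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    atoms = [
        AtomSite(name, "C", residue, seq, chain,
                 [radius * np.cos(2 * np.pi * i / 6),
                  radius * np.sin(2 * np.pi * i / 6), 0.0])
        for i, name in enumerate(names)
    ]
    return StructureModel(atoms)


@pytest.fixture
def hexagon_model():
    return hexagon_ring_model()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
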