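import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

import foes
from foes.docking import FragmentPose


@pytest.fixture(scope="session")
def helix60():
    return foes.ideal_helix(60)


@pytest.fixture(scope="session")
def helix20():
    return foes.ideal_helix(20)


@pytest.fixture(scope="session")
def toy_library():
    return foes.toy_fragment_library()


def make_pose(
    smiles: str,
    anchor_atom: int,
    anchor_pos,
    direction,
    fragment_id: str = "frag",
    window_id: str = "w",
    score: float = -1.0,
) -> FragmentPose:
    """Embed a molecule, then rigidly place it so ``anchor_atom`` sits at
    ``anchor_pos`` with its centroid-outward direction along ``direction``."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = 12345
    assert AllChem.EmbedMolecule(mol, params) == 0
    mol = Chem.RemoveHs(mol)
    conf = mol.GetConformer()
    coords = np.asarray(conf.GetPositions(), dtype=float)

    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    centroid = coords.mean(axis=0)
    current = coords[anchor_atom] - centroid
    norm = np.linalg.norm(current)
    if norm > 1e-9:
        current = current / norm
        # rotate so that `current` aligns with `direction`
        v = np.cross(current, direction)
        c = float(current @ direction)
        if np.linalg.norm(v) < 1e-9:
            rot = np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(direction, direction)
        else:
            vx = np.array(
                [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
            )
            rot = np.eye(3) + vx + vx @ vx / (1 + c)
        coords = (coords - centroid) @ rot.T + centroid
    coords = coords + (np.asarray(anchor_pos, dtype=float) - coords[anchor_atom])
    for i in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(i, coords[i].tolist())
    return FragmentPose(
        fragment_id=fragment_id,
        mol=mol,
        score=score,
        window_id=window_id,
        engine="builtin",
        score_percentile=1.0,
    )
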