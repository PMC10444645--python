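import numpy as np
import pytest

from clashfix.structures import Atom, Structure, infer_topology
from clashfix.synthdata import make_toy_chain, pathological_model


@pytest.fixture(scope="session")
def toy_chain():
    """Clean 6-residue extended chain with its bond graph."""
    s, g, _ = make_toy_chain(6)
    return s, g


@pytest.fixture(scope="session")
def surrogate_model():
    return pathological_model()


def make_atoms(records):
    """Structure from (name, element, xyz[, resnum]) tuples."""
    atoms = []
    for k, rec in enumerate(records):
        name, element, xyz = rec[:3]
        resnum = rec[3] if len(rec) > 3 else 1
        atoms.append(
            Atom(
                serial=k + 1,
                name=name,
                element=element,
                residue_name="UNK",
                residue_number=resnum,
                chain_id="A",
                xyz=np.asarray(xyz, float),
            )
        )
    return Structure(atoms)


@pytest.fixture
def two_atom_factory():
    def build(e1, e2, distance):
        s = make_atoms([(e1, e1, (0.0, 0.0, 0.0)), (e2, e2, (distance, 0.0, 0.0))])
        return s, infer_topology(s)

    return build


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
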