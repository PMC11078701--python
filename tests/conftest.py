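import numpy as np
import pytest

from pasdimer.fixtures import FixtureSpec, build_pas_dimer, build_pas_monomer


@pytest.fixture(scope="session")
def pas_monomer():
    """Default idealized PAS monomer with its ground truth."""
    return build_pas_monomer(FixtureSpec(kind="pas_monomer"))


@pytest.fixture(scope="session")
def alpha3_dimer():
    return build_pas_dimer(FixtureSpec(kind="pas_dimer", interface_element="α3",
                                       parallel=True, separation=3.8))


@pytest.fixture(scope="session")
def alpha1_dimer():
    return build_pas_dimer(FixtureSpec(kind="pas_dimer", interface_element="α1",
                                       parallel=True, separation=3.8))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240404)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def transform_structure(s, R, t):
    """Rigidly move every atom of a Structure (in place)."""
    for chain in s.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.coord = R @ atom.coord + np.asarray(t, dtype=float)


def transform_chain(chain, R, t):
    for res in chain.residues:
        for atom in res.atoms:
            atom.coord = R @ atom.coord + np.asarray(t, dtype=float)
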