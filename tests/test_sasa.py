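"""Solvent-accessible surface area, burial, symmetry expansion."""

import copy

import gemmi
import numpy as np
import pytest

from conftest import random_rotation, transform_chain
from pasdimer.fixtures import build_ideal_chain
from pasdimer.sasa import (buried_fraction, crystal_contact_burial,
                           expand_symmetry, shrake_rupley, spiral_points)
from pasdimer.structures import Atom, Chain, CrystalInfo, Residue, Structure

PROBE = 1.4
R_S = 1.80  # sulfur vdW radius in the default table


def _atom_chain(coords, element="S", name="S"):
    residues = [Residue(author_number=i + 1, res_name="UNK",
                        atoms=[Atom(name=name, element=element, coord=c)])
                for i, c in enumerate(coords)]
    return Chain("A", residues)


def _triples(chain):
    return [(chain, r, a) for r in chain.residues for a in r.atoms]


def _ops(space_group):
    return [(np.array(op.rot) / op.DEN, np.array(op.tran) / op.DEN)
            for op in gemmi.SpaceGroup(space_group).operations()]


def two_sphere_oracle(r1, r2, d, n=200_000):
    """Exposed area of sphere 1 against sphere 2 by dense 1-D numerical
    integration over latitude (the azimuthal integral is exact by symmetry)."""
    theta = (np.arange(n) + 0.5) * np.pi / n
    pts_z = r1 * np.cos(theta)
    pts_rho = r1 * np.sin(theta)
    dist2 = pts_rho ** 2 + (pts_z - d) ** 2
    outside = dist2 > r2 ** 2
    return float((2 * np.pi * r1 ** 2 * np.sin(theta) * outside).sum() * np.pi / n)


def test_single_sphere_matches_closed_form():
    chain = _atom_chain([[0.0, 0.0, 0.0]])
    res = shrake_rupley(_triples(chain), probe=PROBE, n_points=960)
    exact = 4 * np.pi * (R_S + PROBE) ** 2
    assert abs(res.total - exact) / exact < 0.01


def test_disjoint_spheres_are_additive():
    chain = _atom_chain([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
    res = shrake_rupley(_triples(chain), probe=PROBE, n_points=960)
    single = 4 * np.pi * (R_S + PROBE) ** 2
    assert res.total == pytest.approx(2 * single, rel=0.01)
    assert res.atom_areas[0] == pytest.approx(res.atom_areas[1], rel=1e-9)


def test_overlapping_spheres_match_integration_oracle():
    chain = _atom_chain([[0.0, 0.0, 0.0], [0.0, 0.0, 2.0]])
    res = shrake_rupley(_triples(chain), probe=PROBE, n_points=960)
    r = R_S + PROBE
    expected = two_sphere_oracle(r, r, 2.0)
    for area in res.atom_areas:
        assert abs(area - expected) / expected < 0.02


def test_point_density_convergence():
    chain = _atom_chain([[0.0, 0.0, 0.0], [0.0, 0.0, 2.5]])
    a = shrake_rupley(_triples(chain), probe=PROBE, n_points=960).total
    b = shrake_rupley(_triples(chain), probe=PROBE, n_points=1920).total
    assert abs(a - b) / a < 0.005


def test_unknown_element_is_an_error():
    chain = _atom_chain([[0.0, 0.0, 0.0]], element="Xx", name="XX")
    with pytest.raises(ValueError, match="XX"):
        shrake_rupley(_triples(chain))


def test_sasa_invariant_under_rigid_motion(rng):
    chain = build_ideal_chain([("helix", 10, -57.0, -47.0)])
    base = shrake_rupley(_triples(chain), n_points=960).total
    moved = copy.deepcopy(chain)
    transform_chain(moved, random_rotation(rng), [3.0, -11.0, 6.0])
    total = shrake_rupley(_triples(moved), n_points=960).total
    assert abs(total - base) / base < 0.005


def test_spiral_points_are_unit_and_deterministic():
    pts = spiral_points(960)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    np.testing.assert_array_equal(pts, spiral_points(960))


def test_buried_fraction_zero_when_far():
    a = _atom_chain([[0.0, 0.0, 0.0]])
    b = Chain("B", [Residue(author_number=1, res_name="UNK",
                            atoms=[Atom(name="S", element="S",
                                        coord=[100.0, 0.0, 0.0])])])
    s = Structure(id="x", chains=[a, b])
    frac, _ = buried_fraction(s, [(a, a.residues[0])], [(b, b.residues[0])],
                              n_points=960)
    assert frac == pytest.approx(0.0, abs=1e-12)


def test_enclosed_atom_contributes_full_area():
    # central atom of group A caged by a dense shell of group B atoms
    pts = spiral_points(60) * 3.0
    a = _atom_chain([[0.0, 0.0, 0.0]])
    b = Chain("B", [Residue(author_number=i + 1, res_name="UNK",
                            atoms=[Atom(name="S", element="S", coord=c)])
                    for i, c in enumerate(pts)])
    s = Structure(id="cage", chains=[a, b])
    frac, per_res = buried_fraction(s, [(a, a.residues[0])],
                                    [(b, r) for r in b.residues], n_points=960)
    assert frac == pytest.approx(1.0, abs=1e-6)
    iso = 4 * np.pi * (R_S + PROBE) ** 2
    assert per_res[("A", 1, "")] == pytest.approx(iso, rel=0.01)


def test_buried_fraction_requires_disjoint_groups():
    a = _atom_chain([[0.0, 0.0, 0.0]])
    s = Structure(id="x", chains=[a])
    with pytest.raises(ValueError):
        buried_fraction(s, [(a, a.residues[0])], [(a, a.residues[0])])


def test_expand_symmetry_isolated_molecule_in_large_cell():
    chain = _atom_chain([[100.0, 100.0, 100.0]])
    s = Structure(id="p1", chains=[chain],
                  crystal=CrystalInfo("P 1", (200, 200, 200, 90, 90, 90),
                                      _ops("P 1")))
    assert expand_symmetry(s, radius=5.0) == []
    assert crystal_contact_burial(s, "A", n_points=240) == pytest.approx(0.0)


def test_expand_symmetry_mates_round_trip():
    chain = build_ideal_chain([("helix", 8, -57.0, -47.0)])
    # small cell so that symmetry mates genuinely touch
    crystal = CrystalInfo("P 21 21 21", (18.0, 20.0, 22.0, 90.0, 90.0, 90.0),
                          _ops("P 21 21 21"))
    s = Structure(id="tight", chains=[chain], crystal=crystal)
    mates = expand_symmetry(s, radius=5.0)
    assert mates
    M = crystal.orthogonalization_matrix()
    Minv = np.linalg.inv(M)
    for mate in mates:
        rot, tran = crystal.operators[mate.operator_index]
        n = np.array(mate.lattice_translation, dtype=float)
        A = M @ rot @ Minv
        b = M @ (tran + n)
        for ch, ch0 in zip(mate.chains, s.chains):
            for res, res0 in zip(ch.residues, ch0.residues):
                for atom, atom0 in zip(res.atoms, res0.atoms):
                    back = np.linalg.solve(A, atom.coord - b)
                    np.testing.assert_allclose(back, atom0.coord, atol=1e-6)


def test_crystal_contact_burial_positive_in_tight_cell():
    chain = build_ideal_chain([("helix", 8, -57.0, -47.0)])
    crystal = CrystalInfo("P 21 21 21", (18.0, 20.0, 22.0, 90.0, 90.0, 90.0),
                          _ops("P 21 21 21"))
    s = Structure(id="tight", chains=[chain], crystal=crystal)
    frac = crystal_contact_burial(s, "A", n_points=240)
    assert 0.0 < frac <= 1.0
    # restricting to a residue window also stays within [0, 1]
    sub = crystal_contact_burial(s, "A", residue_range=(2, 5), n_points=240)
    assert 0.0 <= sub <= 1.0


def test_missing_crystal_info_is_an_error():
    chain = _atom_chain([[0.0, 0.0, 0.0]])
    with pytest.raises(ValueError):
        expand_symmetry(Structure(id="x", chains=[chain]), radius=5.0)
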