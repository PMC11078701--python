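"""Hydrogen-bond energetics, three-state assignment, element segmentation,
polar contacts."""

import copy

import numpy as np
import pytest

from conftest import random_rotation, transform_chain
from pasdimer.fixtures import build_hairpin, build_ideal_chain
from pasdimer.secondary import (SSAssignment, assign_secondary_structure,
                                find_polar_contacts, hbond_energy,
                                segment_elements)
from pasdimer.structures import Atom, Chain, Residue, Structure


def _residue(number, name, atoms):
    return Residue(author_number=number, res_name=name,
                   atoms=[Atom(name=n, element=n[0], coord=c) for n, c in atoms])


def test_hbond_energy_cancels_for_symmetric_geometry():
    # donor N at origin, CA below → inferred H at (0,0,1); placing C and O
    # symmetrically about the N–H midplane makes all four distances equal
    donor = _residue(1, "ALA", [("N", [0, 0, 0]), ("CA", [0, 0, -1])])
    acceptor = _residue(5, "ALA", [("C", [-1.5, 0, 0.5]), ("O", [1.5, 0, 0.5])])
    assert hbond_energy(donor, acceptor) == pytest.approx(0.0, abs=1e-12)


def test_hbond_energy_in_ideal_helix():
    chain = build_ideal_chain([("helix", 12, -57.0, -47.0)])
    res = chain.residues
    e = hbond_energy(res[4], res[0], donor_prev=res[3])
    assert e < -0.5


def test_hbond_energy_decays_with_distance():
    donor = _residue(1, "ALA", [("N", [0, 0, 0]), ("CA", [0, 0, -1])])
    acceptor = _residue(9, "ALA", [("C", [50, 0, 0]), ("O", [51, 0, 0])])
    assert abs(hbond_energy(donor, acceptor)) < 0.05


def test_proline_cannot_donate():
    chain = build_ideal_chain([("helix", 12, -57.0, -47.0)])
    chain.residues[4].res_name = "PRO"
    assert hbond_energy(chain.residues[4], chain.residues[0]) is None


def test_ideal_helix_interior_labelled_h():
    chain = build_ideal_chain([("helix", 12, -57.0, -47.0)])
    a = assign_secondary_structure(chain)
    assert "".join(a.labels) == "C" + "H" * 10 + "C"
    # every H residue donates or accepts an i±4 bond below the cutoff
    h_idx = [i for i, lab in enumerate(a.labels) if lab == "H"]
    bond_pairs = {(d.author_number, ac.author_number) for d, ac, _ in a.hbonds}
    for i in h_idx:
        num = a.residues[i].author_number
        assert ((num + 4, num) in bond_pairs or (num, num - 4) in bond_pairs
                or (num - 4, num) in bond_pairs or (num, num + 4) in bond_pairs)


def test_hairpin_strands_labelled_e():
    chain = build_hairpin()
    a = assign_secondary_structure(chain)
    labels = "".join(a.labels)
    runs = [r for r in labels.replace("C", " ").split() if set(r) == {"E"}]
    assert len(runs) == 2 and all(len(r) >= 3 for r in runs)


def test_tiny_chain_is_all_coil():
    chain = build_ideal_chain([("helix", 3, -57.0, -47.0)])
    with pytest.warns(UserWarning):
        a = assign_secondary_structure(chain)
    assert a.labels == ["C", "C", "C"]


def test_assignment_invariant_under_rigid_motion(pas_monomer, rng):
    chain, _ = pas_monomer
    base = assign_secondary_structure(chain).labels
    moved = copy.deepcopy(chain)
    transform_chain(moved, random_rotation(rng), [13.0, -8.0, 2.0])
    assert assign_secondary_structure(moved).labels == base


def test_segment_elements_thresholds():
    chain = build_ideal_chain([("helix", 6, -57.0, -47.0)])
    a = SSAssignment(residues=chain.residues, labels=["H"] * 6, hbonds=[])
    els = segment_elements(a, chain)
    assert len(els) == 1 and els[0].kind == "helix" and els[0].sequence_index == 1

    a3 = SSAssignment(residues=chain.residues,
                      labels=["H", "H", "H", "C", "C", "C"], hbonds=[])
    assert segment_elements(a3, chain) == []


def test_segments_partition_residues(pas_monomer):
    chain, _ = pas_monomer
    a = assign_secondary_structure(chain)
    els = segment_elements(a, chain)
    seen = set()
    for el in els:
        ids = {id(r) for r in el.residues}
        assert not (ids & seen)
        seen |= ids


def test_pas_fixture_elements_in_construction_order(pas_monomer):
    chain, truth = pas_monomer
    a = assign_secondary_structure(chain)
    els = segment_elements(a, chain)
    helices = [e for e in els if e.kind == "helix"]
    strands = [e for e in els if e.kind == "strand"]
    assert len(helices) == 3 and len(strands) == 5
    for k, el in enumerate(strands, start=1):
        lo, hi = truth.element_ranges[f"β{k}"]
        assert lo <= el.start.author_number and el.end.author_number <= hi


def _contact_structure(distance):
    a = Chain("A", [_residue(1, "ASN", [("N", [0, 0, 0]), ("CA", [1.5, 0, 0]),
                                        ("C", [2.5, 1, 0]), ("O", [2.5, 2, 0]),
                                        ("ND2", [0, 0, 1.0])])])
    b = Chain("B", [_residue(1, "ALA", [("N", [8, 8, 0]), ("CA", [9, 8, 0]),
                                        ("C", [10, 8, 0]),
                                        ("O", [0, 0, 1.0 + distance])])])
    return Structure(id="pc", chains=[a, b])


def test_polar_contacts_found_and_distance_limited():
    s = _contact_structure(2.9)
    selA = [(s.chains[0].residues[0], s.chains[0].residues[0].atom("ND2"))]
    selB = [(s.chains[1].residues[0], a) for a in s.chains[1].residues[0].atoms]
    contacts = find_polar_contacts(s, selA, selB, d_max=3.5)
    assert len(contacts) == 1
    assert contacts[0].inter_chain
    assert contacts[0].distance == pytest.approx(2.9)
    assert contacts[0].donor_atom.name == "ND2"

    far = _contact_structure(4.5)
    selA = [(far.chains[0].residues[0], far.chains[0].residues[0].atom("ND2"))]
    selB = [(far.chains[1].residues[0], a) for a in far.chains[1].residues[0].atoms]
    assert find_polar_contacts(far, selA, selB, d_max=3.5) == []


def test_polar_contacts_symmetric_up_to_role_swap():
    s = _contact_structure(2.9)
    selA = [(s.chains[0].residues[0], a) for a in s.chains[0].residues[0].atoms]
    selB = [(s.chains[1].residues[0], a) for a in s.chains[1].residues[0].atoms]
    ab = find_polar_contacts(s, selA, selB, d_max=3.5)
    ba = find_polar_contacts(s, selB, selA, d_max=3.5)
    pairs_ab = {frozenset([id(c.donor_atom), id(c.acceptor_atom)]) for c in ab}
    pairs_ba = {frozenset([id(c.donor_atom), id(c.acceptor_atom)]) for c in ba}
    assert pairs_ab == pairs_ba


def test_polar_contacts_empty_selection_rejected():
    s = _contact_structure(2.9)
    with pytest.raises(ValueError):
        find_polar_contacts(s, [], [(s.chains[1].residues[0],
                                     s.chains[1].residues[0].atom("O"))])
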