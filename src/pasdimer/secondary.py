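"""Secondary-structure assignment from backbone hydrogen-bond energetics.

The assignment follows the classic electrostatic hydrogen-bond model:
amide hydrogens are reconstructed from backbone geometry, the
donor–acceptor interaction energy is evaluated as

    E = 0.084 · 332 · (1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN)  kcal/mol

and bonds with E below a cutoff (−0.5 kcal/mol) define n-turns and
bridges, which are reduced to three states: H (helix), E (strand), C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import AxisFit, fit_axis
from .structures import Atom, Chain, Residue, Structure

__all__ = [
    "HBOND_CUTOFF",
    "SSAssignment",
    "SSElement",
    "PolarContact",
    "hbond_energy",
    "assign_secondary_structure",
    "segment_elements",
    "find_polar_contacts",
]

HBOND_CUTOFF = -0.5       # kcal/mol
_E_CLAMP = -9.9
_COUPLING = 0.084 * 332.0  # kcal·Å/mol
MIN_HELIX_LEN = 4
MIN_STRAND_LEN = 3


@dataclass
class SSAssignment:
    residues: list[Residue]
    labels: list[str]                      # one of H, E, C per residue
    hbonds: list[tuple[Residue, Residue, float]]  # (donor, acceptor, energy)

    def label_of(self, residue: Residue) -> str:
        return self.labels[self.residues.index(residue)]


@dataclass
class SSElement:
    kind: str                 # helix | strand
    residues: list[Residue]
    axis: AxisFit
    sequence_index: int = 0   # 1-based among same-kind elements, N→C

    @property
    def start(self) -> Residue:
        return self.residues[0]

    @property
    def end(self) -> Residue:
        return self.residues[-1]

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atom("CA").coord for r in self.residues
                         if r.atom("CA") is not None]).reshape(-1, 3)


@dataclass
class PolarContact:
    donor_residue: Residue
    donor_atom: Atom
    acceptor_residue: Residue
    acceptor_atom: Atom
    distance: float
    inter_chain: bool


def _amide_h(residue: Residue, prev_residue: Residue | None) -> np.ndarray | None:
    """Amide H at 1.0 Å from N, opposite the bisector of N→C(prev) and N→CA."""
    n = residue.atom("N")
    ca = residue.atom("CA")
    if n is None or ca is None:
        return None
    if prev_residue is not None and prev_residue.atom("C") is not None:
        c_prev = prev_residue.atom("C").coord
        v1 = c_prev - n.coord
        v2 = ca.coord - n.coord
        bisector = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
        norm = np.linalg.norm(bisector)
        if norm > 1e-9:
            return n.coord - bisector / norm
    v = n.coord - ca.coord
    return n.coord + v / np.linalg.norm(v)


def hbond_energy(donor_res: Residue, acceptor_res: Residue,
                 donor_prev: Residue | None = None) -> float | None:
    """Backbone N–H···O=C electrostatic energy in kcal/mol.

    ``donor_prev`` supplies the preceding residue's carbonyl carbon used to
    reconstruct the amide hydrogen; without it a cruder N→CA-based
    direction is used.  Returns None when backbone atoms are missing, and
    clamps at −9.9 kcal/mol.  Prolines cannot donate.
    """
    if donor_res.res_name == "PRO":
        return None
    n = donor_res.atom("N")
    c = acceptor_res.atom("C")
    o = acceptor_res.atom("O")
    h = _amide_h(donor_res, donor_prev)
    if n is None or c is None or o is None or h is None:
        return None
    d_on = np.linalg.norm(o.coord - n.coord)
    d_ch = np.linalg.norm(c.coord - h)
    d_oh = np.linalg.norm(o.coord - h)
    d_cn = np.linalg.norm(c.coord - n.coord)
    if min(d_on, d_ch, d_oh, d_cn) < 0.5:
        return _E_CLAMP
    e = _COUPLING * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)
    return max(e, _E_CLAMP)


def _hbond_matrix(residues: list[Residue]) -> dict[tuple[int, int], float]:
    """All (donor index, acceptor index) pairs bonded below the cutoff."""
    ca = np.array([r.atom("CA").coord if r.atom("CA") is not None else
                   [np.nan] * 3 for r in residues])
    bonds: dict[tuple[int, int], float] = {}
    valid = ~np.isnan(ca[:, 0])
    idx = np.nonzero(valid)[0]
    if len(idx) == 0:
        return bonds
    tree = cKDTree(ca[idx])
    for ii, jj in tree.query_pairs(9.0):
        for i, j in ((idx[ii], idx[jj]), (idx[jj], idx[ii])):
            if abs(i - j) < 2:
                continue
            prev = residues[i - 1] if i > 0 else None
            e = hbond_energy(residues[i], residues[j], donor_prev=prev)
            if e is not None and e < HBOND_CUTOFF:
                bonds[(i, j)] = e
    return bonds


def assign_secondary_structure(chain: Chain) -> SSAssignment:
    """Three-state (H/E/C) assignment of a chain.

    Helices require two consecutive n-turns (n = 3, 4 or 5); strands are
    residues participating in parallel or antiparallel bridges.  Chains
    shorter than 5 residues are assigned all-C with a warning.
    """
    residues = chain.polymer_residues()
    n = len(residues)
    labels = ["C"] * n
    if n < 5:
        warnings.warn(f"chain {chain.chain_id}: fewer than 5 residues; all coil")
        return SSAssignment(residues=residues, labels=labels, hbonds=[])
    bonds = _hbond_matrix(residues)

    def hb(donor: int, acceptor: int) -> bool:
        return (donor, acceptor) in bonds

    # n-turns: acceptor i, donor i+k
    for k in (4, 3, 5):
        turns = [i for i in range(n - k) if hb(i + k, i)]
        turn_set = set(turns)
        for i in turns:
            if i - 1 in turn_set:  # two consecutive turns ⇒ minimal helix
                for j in range(i, min(i + k, n)):
                    labels[j] = "H"

    # bridges
    is_bridge = [False] * n
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = (hb(i, j - 1) and hb(j + 1, i)) or (hb(j, i - 1) and hb(i + 1, j))
            antiparallel = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if parallel or antiparallel:
                is_bridge[i] = is_bridge[j] = True
    for i in range(n):
        if is_bridge[i] and labels[i] != "H":
            labels[i] = "E"

    hblist = [(residues[d], residues[a], e) for (d, a), e in sorted(bonds.items())]
    return SSAssignment(residues=residues, labels=labels, hbonds=hblist)


def _element_axis(coords: np.ndarray) -> AxisFit:
    if coords.shape[0] >= 4:
        return fit_axis(coords)
    # short strands: axis from endpoints
    d = coords[-1] - coords[0]
    norm = np.linalg.norm(d)
    direction = d / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    return AxisFit(direction=direction, centroid=coords.mean(axis=0),
                   length=float(norm), linearity=1.0)


def segment_elements(a: SSAssignment, chain: Chain) -> list[SSElement]:
    """Maximal H runs (≥4) → helices, E runs (≥3) → strands, with fitted axes
    and 1-based per-kind sequence indices."""
    elements: list[SSElement] = []
    i = 0
    n = len(a.labels)
    while i < n:
        lab = a.labels[i]
        j = i
        while j < n and a.labels[j] == lab:
            j += 1
        run = a.residues[i:j]
        if lab == "H" and len(run) >= MIN_HELIX_LEN:
            kind = "helix"
        elif lab == "E" and len(run) >= MIN_STRAND_LEN:
            kind = "strand"
        else:
            kind = None
        if kind:
            coords = np.array([r.atom("CA").coord for r in run
                               if r.atom("CA") is not None])
            if coords.shape[0] >= 2:
                elements.append(SSElement(kind=kind, residues=run,
                                          axis=_element_axis(coords)))
        i = j
    counters = {"helix": 0, "strand": 0}
    for el in elements:
        counters[el.kind] += 1
        el.sequence_index = counters[el.kind]
    return elements


def find_polar_contacts(s: Structure,
                        selA: list[tuple[Residue, Atom]],
                        selB: list[tuple[Residue, Atom]],
                        d_max: float = 3.5) -> list[PolarContact]:
    """All N/O atom pairs across two selections within ``d_max`` Å.

    Donor/acceptor assignment is chemical shorthand: when exactly one of
    the pair is a nitrogen it is taken as the donor; otherwise the selA
    atom is reported as donor.  Purely geometric — no angle term.
    """
    polA = [(r, a) for r, a in selA if a.element in ("N", "O")]
    polB = [(r, a) for r, a in selB if a.element in ("N", "O")]
    if not polA or not polB:
        raise ValueError("polar-contact selections must contain N/O atoms")
    chain_of: dict[int, str] = {}
    for ch in s.chains:
        for res in ch.residues:
            chain_of[id(res)] = ch.chain_id
    coordsB = np.array([a.coord for _, a in polB])
    tree = cKDTree(coordsB)
    contacts: list[PolarContact] = []
    for resA, atomA in polA:
        for j in tree.query_ball_point(atomA.coord, d_max):
            resB, atomB = polB[j]
            if resA is resB and atomA is atomB:
                continue
            dist = float(np.linalg.norm(atomA.coord - atomB.coord))
            donor_first = not (atomA.element == "O" and atomB.element == "N")
            dr, da_, ar, aa = ((resA, atomA, resB, atomB) if donor_first
                               else (resB, atomB, resA, atomA))
            contacts.append(PolarContact(
                donor_residue=dr, donor_atom=da_,
                acceptor_residue=ar, acceptor_atom=aa,
                distance=dist,
                inter_chain=chain_of.get(id(resA)) != chain_of.get(id(resB)),
            ))
    return contacts
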