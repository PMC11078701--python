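"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Backbones are built from standard bond lengths/angles and user dihedrals by
internal-coordinate chain extension; a PAS-like monomer is assembled from
ideal elements (three helices + a five-stranded antiparallel sheet laid out
in the canonical 2-5-1-4-3 spatial order) joined by straight geometric
connector loops.  Dimers place a second copy by an exact two-fold rotation
so that a chosen element (α1 or α3) forms the interface at a chosen
separation, either parallel or antiparallel.  Synthetic MSAs plant N-cap
motif categories at exact counts (largest-remainder rounding) and control
mean pairwise identity.

Everything is deterministic: identical spec + seed gives byte-identical
output.  Loops are geometric, not chemical; side chains are limited to CB
plus the N-cap serine OG — the only side-chain-dependent check downstream.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import fit_axis
from .msa import Msa
from .secondary import HBOND_CUTOFF, hbond_energy
from .structures import Atom, Chain, Residue, Structure

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "build_ideal_chain",
    "build_pas_monomer",
    "build_pas_dimer",
    "build_msa",
]

# standard backbone geometry (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.8
B_CA_CB, A_C_CA_CB, T_N_C_CA_CB = 1.530, 110.6, 122.6
B_CB_OG, A_CA_CB_OG = 1.417, 110.8

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0

ONE_TO_THREE = {
    "A": "ALA", "G": "GLY", "L": "LEU", "S": "SER", "T": "THR",
    "N": "ASN", "D": "ASP", "I": "ILE", "M": "MET", "V": "VAL",
    "P": "PRO", "E": "GLU", "Q": "GLN", "H": "HIS", "K": "LYS",
    "R": "ARG", "F": "PHE", "Y": "TYR", "W": "TRP", "C": "CYS",
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    kind: str                               # helix | hairpin | pas_monomer | pas_dimer | msa
    rng_seed: int = 0
    # geometry
    helix_length: int = 14
    strand_length: int = 7
    n_strands: int = 5
    interface_element: str = "α3"           # α1 | α3 (pas_dimer)
    parallel: bool = True
    separation: float = 3.8                 # Å, min inter-chain heavy-atom distance
    rotation_deg: float = 0.0               # global rotation about the dimer axis
    # msa
    n_records: int = 100
    seq_length: int = 80
    identity_target: float = 90.0           # mean pairwise %
    capping_box_freq: float = 0.9
    non_traditional_freq: float = 0.08
    preceding_li_freq: float = 0.9
    preceding_mv_freq: float = 0.08


@dataclass
class GroundTruth:
    kind: str
    rng_seed: int = 0
    element_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    sheet_order: str = ""
    dimer_class: str = ""
    parallel: bool | None = None
    interface_element: str = ""
    ncap_class: str = ""
    ncap_residue_number: int | None = None
    preceding_class: str = ""
    msa_columns: dict[str, int] = field(default_factory=dict)
    msa_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = {kk: list(vv) if isinstance(vv, tuple) else vv
                      for kk, vv in v.items()} if isinstance(v, dict) else v
        return out


# ---------------------------------------------------------------- backbone

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: new atom at given internal coordinates from frame a-b-c."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(tor),
                  bond * np.sin(ang) * np.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(phis: Sequence[float], psis: Sequence[float],
                    names: Sequence[str], start_number: int = 1) -> list[Residue]:
    """Residues with ideal N/CA/C/O (+CB for non-Gly) from per-residue φ/ψ."""
    n_res = len(phis)
    assert len(psis) == n_res and len(names) == n_res
    coords: list[dict[str, np.ndarray]] = []
    for i in range(n_res):
        if i == 0:
            N = np.zeros(3)
            CA = np.array([B_N_CA, 0.0, 0.0])
            a = np.radians(180.0 - A_N_CA_C)
            C = CA + B_CA_C * np.array([np.cos(a), np.sin(a), 0.0])
        else:
            prev = coords[i - 1]
            N = _place(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psis[i - 1])
            CA = _place(prev["CA"], prev["C"], N, B_N_CA, A_C_N_CA, 180.0)
            C = _place(prev["C"], N, CA, B_CA_C, A_N_CA_C, phis[i])
        O = _place(N, CA, C, B_C_O, A_CA_C_O, psis[i] + 180.0)
        coords.append({"N": N, "CA": CA, "C": C, "O": O})
        if names[i] != "GLY":
            coords[i]["CB"] = _place(N, C, CA, B_CA_CB, A_C_CA_CB, T_N_C_CA_CB)
    residues = []
    for i, atom_map in enumerate(coords):
        atoms = [Atom(name=name, element=name[0], coord=pos)
                 for name, pos in atom_map.items()]
        residues.append(Residue(author_number=start_number + i,
                                res_name=names[i], atoms=atoms))
    return residues


def build_ideal_chain(segments: Sequence[tuple[str, int, float, float]],
                      chain_id: str = "A", start_number: int = 1,
                      sequence: str | None = None) -> Chain:
    """Ideal backbone from (kind, length, φ, ψ) segments (ω = 180°).

    ``sequence`` optionally supplies 1-letter residue names (default Ala).
    """
    phis: list[float] = []
    psis: list[float] = []
    for kind, length, phi, psi in segments:
        if length < 1:
            raise ValueError(f"segment length {length} < 1")
        if not (-180.0 < phi <= 180.0 and -180.0 < psi <= 180.0):
            raise ValueError("dihedrals must lie in (-180, 180]")
        phis.extend([phi] * length)
        psis.extend([psi] * length)
    names = (["ALA"] * len(phis) if sequence is None
             else [ONE_TO_THREE[c] for c in sequence])
    if len(names) != len(phis):
        raise ValueError("sequence length does not match segment lengths")
    residues = _build_backbone(phis, psis, names, start_number=start_number)
    return Chain(chain_id=chain_id, residues=residues)


# ------------------------------------------------------------- rigid utils

def _rot_about(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _transform_residues(residues: list[Residue], R: np.ndarray,
                        t: np.ndarray) -> None:
    for res in residues:
        for atom in res.atoms:
            atom.coord = R @ atom.coord + t


def _residue_coords(residues: list[Residue]) -> np.ndarray:
    return np.array([a.coord for r in residues for a in r.atoms])


def _orient_to_z(residues: list[Residue]) -> None:
    """Rotate/translate a block so its CA axis runs along +z through origin."""
    ca = np.array([r.atom("CA").coord for r in residues])
    ax = fit_axis(ca)
    v = ax.direction
    z = np.array([0.0, 0.0, 1.0])
    cross = np.cross(v, z)
    norm = np.linalg.norm(cross)
    if norm < 1e-9:
        R = np.eye(3) if v[2] > 0 else _rot_about([1, 0, 0], 180.0)
    else:
        angle = np.degrees(np.arctan2(norm, float(np.dot(v, z))))
        R = _rot_about(cross, angle)
    _transform_residues(residues, R, np.zeros(3))
    centroid = np.array([r.atom("CA").coord for r in residues]).mean(axis=0)
    _transform_residues(residues, np.eye(3), -centroid)


# -------------------------------------------------------------- sheet search

def _strand_hbond(donor_res: Residue, donor_prev: Residue | None,
                  acceptor_res: Residue) -> bool:
    e = hbond_energy(donor_res, acceptor_res, donor_prev=donor_prev)
    return e is not None and e < HBOND_CUTOFF


def _pair_bridge_score(A: list[Residue], B: list[Residue]) -> tuple[int, float]:
    """Antiparallel bridge residues between two strands (higher is better)."""
    def hb(X, i, Y, j):
        prev = X[i - 1] if i > 0 else None
        return _strand_hbond(X[i], prev, Y[j])

    bridged_a, bridged_b = set(), set()
    energy = 0.0
    # only interior residues count: edge-residue amide geometry changes once
    # connector loops are attached, so edge bridges are not construction-stable
    for i in range(1, len(A) - 1):
        for j in range(1, len(B) - 1):
            narrow = hb(A, i, B, j) and hb(B, j, A, i)
            wide = hb(A, i - 1, B, j + 1) and hb(B, j - 1, A, i + 1)
            if narrow or wide:
                bridged_a.add(i)
                bridged_b.add(j)
                e = hbond_energy(A[i], B[j], donor_prev=A[i - 1])
                energy += e if e is not None else 0.0
    return len(bridged_a) + len(bridged_b), energy


def _placed_strand(template: list[Residue], up: bool, x: float,
                   rotz: float, dz: float) -> list[Residue]:
    block = copy.deepcopy(template)
    R = _rot_about([0, 0, 1], rotz)
    if not up:
        R = R @ _rot_about([1, 0, 0], 180.0)
    _transform_residues(block, R, np.array([x, 0.0, dz]))
    return block


def _optimize_neighbor(prev_block: list[Residue], template: list[Residue],
                       up: bool, x: float) -> list[Residue]:
    """Grid-search roll and axial shift of a new strand against its neighbour,
    maximizing the number of inter-strand bridge residues."""
    best = None
    for rotz in range(0, 360, 10):
        for dz in np.arange(-3.0, 3.01, 0.25):
            cand = _placed_strand(template, up, x, float(rotz), float(dz))
            score = _pair_bridge_score(prev_block, cand)
            key = (score[0], -score[1])
            if best is None or key > best[0]:
                best = (key, float(rotz), float(dz))
    # local refinement
    rot0, dz0 = best[1], best[2]
    for rotz in np.arange(rot0 - 8, rot0 + 8.01, 2.0):
        for dz in np.arange(dz0 - 0.25, dz0 + 0.2501, 0.05):
            cand = _placed_strand(template, up, x, float(rotz), float(dz))
            score = _pair_bridge_score(prev_block, cand)
            key = (score[0], -score[1])
            if key > best[0]:
                best = (key, float(rotz), float(dz))
    return _placed_strand(template, up, x, best[1], best[2])


# ------------------------------------------------------------------- loops

def _straight_loop(start: np.ndarray, end: np.ndarray, start_number: int,
                   bulge: float = 3.0) -> list[Residue]:
    """Straight geometric connector (Gly backbone); chemistry ignored."""
    d = float(np.linalg.norm(end - start))
    n = max(1, int(round(d / 3.4)) - 1)
    u = (end - start) / d
    ref = np.array([0.0, -1.0, 0.0])
    p = ref - np.dot(ref, u) * u
    if np.linalg.norm(p) < 1e-6:
        p = np.array([1.0, 0.0, 0.0]) - u[0] * u
    p /= np.linalg.norm(p)
    residues = []
    for k in range(1, n + 1):
        t = k / (n + 1)
        center = start + t * (end - start) + p * bulge * np.sin(np.pi * t)
        atoms = [
            Atom(name="N", element="N", coord=center - 0.6 * u),
            Atom(name="CA", element="C", coord=center),
            Atom(name="C", element="C", coord=center + 0.6 * u),
            Atom(name="O", element="O", coord=center + 0.6 * u + 1.23 * p),
        ]
        residues.append(Residue(author_number=start_number + k - 1,
                                res_name="GLY", atoms=atoms))
    return residues


def _roll_flat_face(block: list[Residue], facing: float) -> None:
    """Roll a z-oriented helix about its own axis so its flattest face points
    along ±x (``facing``): dimer interfaces pack faces, not single knobs."""
    coords = _residue_coords(block)
    centroid = coords.mean(axis=0)
    best = None
    for roll in range(0, 360, 5):
        R = _rot_about([0, 0, 1], float(roll))
        x = facing * ((coords - centroid) @ R.T)[:, 0]
        n_face = int((x > x.max() - 1.2).sum())
        key = (-n_face, x.max())
        if best is None or key < best[0]:
            best = (key, float(roll))
    R = _rot_about([0, 0, 1], best[1])
    _transform_residues(block, R, centroid - R @ centroid)


# ------------------------------------------------------------ alpha1 block

def _chi1_rotamer_og(residue: Residue, target: np.ndarray) -> np.ndarray:
    """Serine OG at the staggered χ1 closest to a target atom position."""
    n, ca, cb = (residue.atom(x).coord for x in ("N", "CA", "CB"))
    best = None
    for chi in (-60.0, 60.0, 180.0):
        og = _place(n, ca, cb, B_CB_OG, A_CA_CB_OG, chi)
        d = np.linalg.norm(og - target)
        if best is None or d < best[0]:
            best = (d, og)
    return best[1]


def _build_alpha1_block(helix_length: int) -> tuple[list[Residue], int]:
    """Gly-Leu-Ser + ideal helix, with the serine tuned to act as an N-cap.

    The serine's φ/ψ are grid-searched so that (i) its carbonyl accepts the
    first helical turn (making the serine the residue immediately before
    the first H-labelled residue) and (ii) its OG, at the best staggered
    rotamer, caps the backbone N of the second/third helical residue.
    Returns (residues, index of first helical residue in the block).
    """
    L = helix_length
    names = ["GLY", "LEU", "SER"] + ["ALA"] * L
    best = None
    for phi_s in np.arange(-160.0, -39.9, 10.0):
        for psi_s in np.arange(-80.0, 180.1, 10.0):
            phis = [-120.0, -120.0, float(phi_s)] + [HELIX_PHI] * L
            psis = [140.0, 140.0, float(psi_s)] + [HELIX_PSI] * L
            res = _build_backbone(phis, psis, names)
            # engineered first turn: donor = 4th helical residue, acceptor = Ser
            e_cap = hbond_energy(res[6], res[2], donor_prev=res[5])
            if e_cap is None or e_cap >= HBOND_CUTOFF:
                continue
            # guards: no turn may start before the serine
            bad = False
            for donor_i, acc_i in ((4, 1), (5, 1), (6, 1), (5, 0)):
                e = hbond_energy(res[donor_i], res[acc_i], donor_prev=res[donor_i - 1])
                if e is not None and e < HBOND_CUTOFF:
                    bad = True
                    break
            if bad:
                continue
            # capping bond: Ser OG to backbone N of helix residue 2 or 3
            targets = [res[4].atom("N").coord, res[5].atom("N").coord]
            dists = []
            for tgt in targets:
                og = _chi1_rotamer_og(res[2], tgt)
                dists.append(np.linalg.norm(og - tgt))
            d = min(dists)
            if d > 3.4:
                continue
            key = abs(d - 3.0)
            if best is None or key < best[0]:
                best = (key, float(phi_s), float(psi_s))
    if best is None:
        raise RuntimeError("could not engineer an N-cap geometry")
    _, phi_s, psi_s = best
    phis = [-120.0, -120.0, phi_s] + [HELIX_PHI] * L
    psis = [140.0, 140.0, psi_s] + [HELIX_PSI] * L
    res = _build_backbone(phis, psis, names)
    tgt4, tgt5 = res[4].atom("N").coord, res[5].atom("N").coord
    og4 = _chi1_rotamer_og(res[2], tgt4)
    og5 = _chi1_rotamer_og(res[2], tgt5)
    og = og4 if np.linalg.norm(og4 - tgt4) <= np.linalg.norm(og5 - tgt5) else og5
    res[2].atoms.append(Atom(name="OG", element="O", coord=og))
    return res, 3


def build_hairpin(strand_length: int = 7) -> Chain:
    """Two-strand antiparallel hairpin with optimized inter-strand register."""
    template = build_ideal_chain(
        [("strand", strand_length, STRAND_PHI, STRAND_PSI)]).residues
    _orient_to_z(template)
    first = _placed_strand(template, True, 0.0, 0.0, 0.0)
    second = _optimize_neighbor(first, template, False, SHEET_SPACING)
    first = _optimize_neighbor(second, template, True, 0.0)
    loop = _straight_loop(first[-1].atom("C").coord, second[0].atom("N").coord, 1)
    residues = first + loop + second
    number = _renumber(residues, 1)
    return Chain(chain_id="A", residues=residues)


# --------------------------------------------------------------- pas monomer

# slot (left→right across the sheet) → sequence strand index, canonical order
SHEET_SLOTS_5 = (2, 5, 1, 4, 3)
SHEET_SLOTS_4 = (2, 4, 1, 3)
SHEET_SPACING = 4.8

_MONOMER_CACHE: dict[tuple, tuple[Chain, GroundTruth]] = {}


def _renumber(residues: list[Residue], start: int) -> int:
    for i, r in enumerate(residues):
        r.author_number = start + i
    return start + len(residues)


def build_pas_monomer(spec: FixtureSpec) -> tuple[Chain, GroundTruth]:
    """Idealized PAS-like monomer with ground-truth element labels.

    Sequence order: [tail+N-cap+α1], β1, β2, α2, α3, β3, β4(, β5) with the
    strands placed side-by-side as an antiparallel sheet in the canonical
    2-5-1-4-3 spatial order (or 2-4-1-3 when ``n_strands=4``), α1 on the
    far side of the sheet's first slot and α3 beyond its last slot.
    """
    if spec.kind not in ("pas_monomer", "pas_dimer"):
        raise ValueError("spec.kind must be pas_monomer (or pas_dimer)")
    if spec.n_strands not in (4, 5):
        raise ValueError("only 4- or 5-strand sheets are supported")
    key = (spec.n_strands, spec.strand_length, spec.helix_length)
    if key in _MONOMER_CACHE:
        chain, truth = _MONOMER_CACHE[key]
        return copy.deepcopy(chain), copy.deepcopy(truth)

    slots = SHEET_SLOTS_5 if spec.n_strands == 5 else SHEET_SLOTS_4
    sheet_order = "-".join(str(s) for s in slots)

    # strand template along +z
    template = build_ideal_chain(
        [("strand", spec.strand_length, STRAND_PHI, STRAND_PSI)]).residues
    _orient_to_z(template)

    # place strands slot by slot, optimizing H-bond register to the neighbour
    placed_by_slot: list[list[Residue]] = []
    for k in range(len(slots)):
        up = (k % 2 == 0)
        x = SHEET_SPACING * k
        if k == 0:
            placed_by_slot.append(_placed_strand(template, up, x, 0.0, 0.0))
        else:
            placed_by_slot.append(
                _optimize_neighbor(placed_by_slot[-1], template, up, x))
            if k == 1:
                # the first strand's roll was arbitrary; re-optimize it
                # against its now-placed neighbour
                placed_by_slot[0] = _optimize_neighbor(
                    placed_by_slot[1], template, True, 0.0)
    strand_of_seq = {seq_idx: placed_by_slot[slot]
                     for slot, seq_idx in enumerate(slots)}

    # helices
    a1_block, a1_first_h = _build_alpha1_block(spec.helix_length)
    _orient_to_z(a1_block)
    _roll_flat_face(a1_block, facing=-1.0)
    _transform_residues(a1_block, np.eye(3), np.array([-8.0, 5.0, 0.0]))

    a2_block = build_ideal_chain([("helix", 7, HELIX_PHI, HELIX_PSI)]).residues
    _orient_to_z(a2_block)
    _transform_residues(a2_block, _rot_about([0, 1, 0], 90.0),
                        np.array([SHEET_SPACING * (len(slots) - 1) / 2.0, 9.0, 0.0]))

    a3_block = build_ideal_chain([("helix", 10, HELIX_PHI, HELIX_PSI)]).residues
    _orient_to_z(a3_block)
    _roll_flat_face(a3_block, facing=1.0)
    x_a3 = SHEET_SPACING * (len(slots) - 1) + 6.0
    _transform_residues(a3_block, np.eye(3), np.array([x_a3, 3.0, 0.0]))

    # assemble in sequence order with straight connector loops
    seq_blocks: list[tuple[str, list[Residue]]] = [("α1", a1_block)]
    seq_blocks.append(("β1", strand_of_seq[1]))
    seq_blocks.append(("β2", strand_of_seq[2]))
    seq_blocks.append(("α2", a2_block))
    seq_blocks.append(("α3", a3_block))
    for b in range(3, len(slots) + 1):
        seq_blocks.append((f"β{b}", strand_of_seq[b]))

    residues: list[Residue] = []
    element_ranges: dict[str, tuple[int, int]] = {}
    number = 1
    for idx, (label, block) in enumerate(seq_blocks):
        if idx > 0:
            prev_c = residues[-1].atom("C").coord
            next_n = block[0].atom("N").coord
            loop = _straight_loop(prev_c, next_n, number)
            number = _renumber(loop, number)
            residues.extend(loop)
        number = _renumber(block, number)
        if label == "α1":
            # ground-truth helix excludes the tail/cap and the last residue
            element_ranges[label] = (block[a1_first_h].author_number,
                                     block[-2].author_number)
            ncap_number = block[a1_first_h - 1].author_number
        elif label.startswith("α"):
            element_ranges[label] = (block[1].author_number,
                                     block[-2].author_number)
        else:
            element_ranges[label] = (block[0].author_number,
                                     block[-1].author_number)
        residues.extend(block)

    chain = Chain(chain_id="A", residues=residues)
    truth = GroundTruth(kind="pas_monomer", rng_seed=spec.rng_seed,
                        element_ranges=element_ranges,
                        sheet_order=sheet_order,
                        ncap_class="capping_box",
                        ncap_residue_number=ncap_number,
                        preceding_class="LI")
    _MONOMER_CACHE[key] = (copy.deepcopy(chain), copy.deepcopy(truth))
    return chain, truth


# ----------------------------------------------------------------- pas dimer

def _min_interchain_distance(a: np.ndarray, b: np.ndarray) -> float:
    tree = cKDTree(a)
    d, _ = tree.query(b, k=1)
    return float(d.min())


def build_pas_dimer(spec: FixtureSpec) -> tuple[Structure, GroundTruth]:
    """Two-fold symmetric PAS dimer with a chosen interface element,
    orientation, and minimum inter-chain separation (within 0.3 Å)."""
    if spec.separation < 2.5:
        raise ValueError("separation below 2.5 Å would clash")
    chain_a, truth_m = build_pas_monomer(
        FixtureSpec(kind="pas_monomer", n_strands=spec.n_strands,
                    strand_length=spec.strand_length,
                    helix_length=spec.helix_length))

    lo, hi = truth_m.element_ranges[spec.interface_element]
    elem_res = [r for r in chain_a.residues if lo <= r.author_number <= hi]
    elem_centroid = np.array([r.atom("CA").coord for r in elem_res]).mean(axis=0)
    coords_a = _residue_coords(chain_a.residues)
    sign = 1.0 if spec.interface_element == "α3" else -1.0

    # two-fold axis: parallel dimers rotate about a z-parallel line (keeps
    # N→C direction), antiparallel about a y-parallel line (flips it)
    axis = np.array([0.0, 0.0, 1.0]) if spec.parallel else np.array([0.0, 1.0, 0.0])
    R = _rot_about(axis, 180.0)
    y0 = elem_centroid[1]

    def min_dist_at(x0: float) -> float:
        c = np.array([x0, y0, 0.0])
        moved = (coords_a - c) @ R.T + c
        return _min_interchain_distance(coords_a, moved)

    lo_x = elem_centroid[0]
    hi_x = elem_centroid[0] + sign * 40.0
    if (min_dist_at(hi_x) - spec.separation) < 0:
        raise RuntimeError("could not bracket the requested separation")
    for _ in range(60):
        mid = 0.5 * (lo_x + hi_x)
        if min_dist_at(mid) < spec.separation:
            lo_x = mid
        else:
            hi_x = mid
    x0 = 0.5 * (lo_x + hi_x)

    c = np.array([x0, y0, 0.0])
    chain_b = copy.deepcopy(chain_a)
    chain_b.chain_id = "B"
    _transform_residues(chain_b.residues, R, c - R @ c)

    structure = Structure(id=f"pas_dimer_{spec.interface_element}"
                             f"_{'par' if spec.parallel else 'anti'}",
                          chains=[chain_a, chain_b])
    if spec.rotation_deg:
        Rg = _rot_about(axis, spec.rotation_deg)
        for ch in structure.chains:
            _transform_residues(ch.residues, Rg, c - Rg @ c)

    far = spec.separation > 8.0
    if far:
        dimer_class = "not_dimer"
    elif not spec.parallel:
        dimer_class = "other_interface"
    elif spec.interface_element == "α3":
        dimer_class = "alpha3_interface"
    else:
        dimer_class = "alpha1_interface"
    truth = GroundTruth(kind="pas_dimer", rng_seed=spec.rng_seed,
                        element_ranges=truth_m.element_ranges,
                        sheet_order=truth_m.sheet_order,
                        dimer_class=dimer_class, parallel=spec.parallel,
                        interface_element=spec.interface_element,
                        ncap_class=truth_m.ncap_class,
                        ncap_residue_number=truth_m.ncap_residue_number,
                        preceding_class=truth_m.preceding_class)
    return structure, truth


# ----------------------------------------------------------------------- msa

def _largest_remainder(freqs: dict[str, float], n: int) -> dict[str, int]:
    floors = {k: int(np.floor(f * n)) for k, f in freqs.items()}
    remainder = n - sum(floors.values())
    order = sorted(freqs, key=lambda k: (-(freqs[k] * n - floors[k]), k))
    for k in order[:remainder]:
        floors[k] += 1
    return floors


_CLASS_RESIDUES = {
    "capping_box": "STND",
    "non_traditional": "GPEQH",
    "absent": "AKRFWYC",
    "LI": "LI",
    "MV": "MV",
    "other": "AKRFWY",
}


def build_msa(spec: FixtureSpec) -> tuple[Msa, GroundTruth]:
    """Synthetic MSA with planted N-cap motif classes at exact counts and a
    controlled mean pairwise identity.

    The N-cap column and the preceding column are excluded from mutation;
    class counts follow largest-remainder rounding of the requested
    frequencies, so a frequency of 0.9 over 100 records plants exactly 90.
    """
    if spec.kind != "msa":
        raise ValueError("spec.kind must be msa")
    for f in (spec.capping_box_freq, spec.non_traditional_freq,
              spec.preceding_li_freq, spec.preceding_mv_freq):
        if not 0.0 <= f <= 1.0:
            raise ValueError("frequencies must lie in [0, 1]")
    if spec.capping_box_freq + spec.non_traditional_freq > 1.0 + 1e-9:
        raise ValueError("N-cap class frequencies exceed 1")
    if spec.preceding_li_freq + spec.preceding_mv_freq > 1.0 + 1e-9:
        raise ValueError("preceding class frequencies exceed 1")
    rng = np.random.default_rng(spec.rng_seed)
    L, n = spec.seq_length, spec.n_records
    ncap_col, pre_col = L // 2, L // 2 - 2
    protected = {ncap_col, pre_col}
    aas = list(AMINO_ACIDS)
    seed_seq = rng.choice(aas, size=L)

    # mutation fraction so that E[pairwise identity] ≈ target
    p = 1.0 - np.sqrt(spec.identity_target / 100.0)
    k_mut = int(round(p * (L - len(protected))))
    mutable = np.array([i for i in range(L) if i not in protected])

    ncap_counts = _largest_remainder(
        {"capping_box": spec.capping_box_freq,
         "non_traditional": spec.non_traditional_freq,
         "absent": 1.0 - spec.capping_box_freq - spec.non_traditional_freq}, n)
    pre_counts = _largest_remainder(
        {"LI": spec.preceding_li_freq, "MV": spec.preceding_mv_freq,
         "other": 1.0 - spec.preceding_li_freq - spec.preceding_mv_freq}, n)
    ncap_classes = [k for k, c in sorted(ncap_counts.items()) for _ in range(c)]
    pre_classes = [k for k, c in sorted(pre_counts.items()) for _ in range(c)]
    rng.shuffle(ncap_classes)
    rng.shuffle(pre_classes)

    records = []
    for r in range(n):
        seq = seed_seq.copy()
        if k_mut:
            sites = rng.choice(mutable, size=k_mut, replace=False)
            for s in sites:
                choices = [a for a in aas if a != seq[s]]
                seq[s] = choices[rng.integers(len(choices))]
        pool = _CLASS_RESIDUES[ncap_classes[r]]
        seq[ncap_col] = pool[rng.integers(len(pool))]
        pool = _CLASS_RESIDUES[pre_classes[r]]
        seq[pre_col] = pool[rng.integers(len(pool))]
        records.append((f"seq{r:04d}", "".join(seq)))

    msa = Msa(records=records, query_id="seq0000")
    truth = GroundTruth(kind="msa", rng_seed=spec.rng_seed,
                        msa_columns={"ncap": ncap_col, "preceding": pre_col},
                        msa_counts={"capping_box": ncap_counts["capping_box"],
                                    "non_traditional": ncap_counts["non_traditional"],
                                    "absent": ncap_counts["absent"],
                                    "preceding_LI": pre_counts["LI"],
                                    "preceding_MV": pre_counts["MV"],
                                    "preceding_other": pre_counts["other"]})
    return msa, truth
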