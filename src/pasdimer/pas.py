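"""PAS-fold recognition and canonical element labelling.

A PAS sensor domain is recognised as a single five-stranded antiparallel
β-sheet whose spatial strand order (by sequence index) is the canonical
2-5-1-4-3, flanked by at least three helices: a long N-terminal α1 (the
"periplasmic" helix in extracytoplasmic sensors), α2, and α3.  The module
also detects the α1 N-cap motif — the residue just before the helix whose
side chain caps the exposed amides of the first helical turn — both
structurally (capping hydrogen bond) and at the sequence-category level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .secondary import (SSAssignment, SSElement, assign_secondary_structure,
                        segment_elements)
from .structures import Chain, Residue

__all__ = [
    "NCAP_RULES",
    "THREE_TO_ONE",
    "NcapMotif",
    "PasAnnotation",
    "SheetTopologyError",
    "order_sheet_strands",
    "annotate_pas",
    "detect_ncap",
    "normalize_sheet_order",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# N-cap sequence categories.  capping_box: side chains that form the
# canonical reciprocal cap (Ser/Thr/Asn/Asp); non_traditional: residues seen
# in known N-caps that are not classic capping boxes.
NCAP_RULES = {
    "capping_box": frozenset("STND"),
    "non_traditional": frozenset("GPEQH"),
    "preceding_LI": frozenset("LI"),
    "preceding_MV": frozenset("MV"),
}

CANONICAL_ORDER = "2-5-1-4-3"


class SheetTopologyError(ValueError):
    """Strands do not form a single unbranched sheet."""


@dataclass
class NcapMotif:
    ncap_residue: Residue | None
    ncap_class: str                   # capping_box | non_traditional | absent
    capping_hbond: bool | None        # None = undetermined (missing atoms)
    preceding_residue: str            # 1-letter code of N″, or ""
    preceding_class: str              # LI | MV | other
    reason: str = ""


@dataclass
class PasAnnotation:
    is_pas: bool
    alpha: dict[str, SSElement] = field(default_factory=dict)   # α1..α3
    beta: dict[str, SSElement] = field(default_factory=dict)    # β1..β5
    sheet_order: str = ""
    ncap: NcapMotif | None = None
    reason: str = ""


def normalize_sheet_order(order: str) -> str:
    """Canonical representative of a sheet-order string: the lexicographically
    smaller of the string and its reverse (edge choice is arbitrary)."""
    parts = order.split("-")
    rev = "-".join(reversed(parts))
    return min(order, rev)


def _min_ca_distance(a: SSElement, b: SSElement) -> float:
    ca_a = a.ca_coords()
    ca_b = b.ca_coords()
    d = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


def _hbond_count(a: SSElement, b: SSElement,
                 hbonds: list[tuple[Residue, Residue, float]]) -> int:
    set_a = {id(r) for r in a.residues}
    set_b = {id(r) for r in b.residues}
    n = 0
    for donor, acceptor, _ in hbonds:
        if (id(donor) in set_a and id(acceptor) in set_b) or \
           (id(donor) in set_b and id(acceptor) in set_a):
            n += 1
    return n


def order_sheet_strands(strands: list[SSElement],
                        hbonds: list[tuple[Residue, Residue, float]] | None = None,
                        adjacency_cutoff: float = 5.5,
                        min_hbonds: int = 2) -> str:
    """Spatial order of a sheet's strands, as sequence indices along the sheet.

    Strands are adjacent when their mean nearest-CA distance is below
    ``adjacency_cutoff`` Å and (when a hydrogen-bond list is supplied) at
    least ``min_hbonds`` inter-strand backbone bonds connect them.  The
    sheet must form a single unbranched path; the output is orientation
    normalized (a string equals its reversal's normalization).
    """
    if len(strands) < 2:
        raise ValueError("need at least 2 strands")
    n = len(strands)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if _min_ca_distance(strands[i], strands[j]) >= adjacency_cutoff:
                continue
            if hbonds is not None and _hbond_count(strands[i], strands[j], hbonds) < min_hbonds:
                continue
            adj[i].append(j)
            adj[j].append(i)

    # connectivity
    seen = {0}
    stack = [0]
    while stack:
        for j in adj[stack.pop()]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    if len(seen) != n:
        comps = sorted(seen), sorted(set(range(n)) - seen)
        raise SheetTopologyError(f"strands form multiple sheets: {comps}")
    degrees = [len(a) for a in adj]
    if any(d > 2 for d in degrees) or degrees.count(1) != 2:
        raise SheetTopologyError(f"sheet adjacency is branched (degrees {degrees})")

    start = degrees.index(1)
    path = [start]
    prev = -1
    while len(path) < n:
        nxt = [j for j in adj[path[-1]] if j != prev]
        prev = path[-1]
        path.append(nxt[0])
    order = "-".join(str(strands[i].sequence_index) for i in path)
    return normalize_sheet_order(order)


def detect_ncap(chain: Chain, helix: SSElement,
                hbond_cutoff: float = 3.5) -> NcapMotif:
    """N-cap motif of a helix: sequence class of the N′ residue (the one just
    before the first helical residue), the structural capping hydrogen bond
    (side-chain O/N of N′ or N1 within ``hbond_cutoff`` Å of the backbone N
    of N2 or N3), and the class of the N″ residue preceding the cap."""
    residues = chain.polymer_residues()
    start_idx = next((i for i, r in enumerate(residues)
                      if r is helix.residues[0]), None)
    if start_idx is None:
        raise ValueError("helix start not found in chain")
    if start_idx == 0:
        return NcapMotif(ncap_residue=None, ncap_class="absent",
                         capping_hbond=None, preceding_residue="",
                         preceding_class="other", reason="terminal")
    ncap_res = residues[start_idx - 1]
    one = THREE_TO_ONE.get(ncap_res.res_name, "X")
    if one in NCAP_RULES["capping_box"]:
        ncap_class = "capping_box"
    elif one in NCAP_RULES["non_traditional"]:
        ncap_class = "non_traditional"
    else:
        ncap_class = "absent"

    if start_idx >= 2:
        pre = THREE_TO_ONE.get(residues[start_idx - 2].res_name, "X")
    else:
        pre = ""
    if pre in NCAP_RULES["preceding_LI"]:
        pre_class = "LI"
    elif pre in NCAP_RULES["preceding_MV"]:
        pre_class = "MV"
    else:
        pre_class = "other"

    # structural capping bond: side chain of N′ or N1 to backbone N of N2/N3
    donors = ncap_res.sidechain_atoms() + helix.residues[0].sidechain_atoms()
    donors = [a for a in donors if a.element in ("N", "O")]
    targets = [helix.residues[i].atom("N") for i in (1, 2)
               if i < len(helix.residues) and helix.residues[i].atom("N")]
    capping: bool | None
    if not donors or not targets:
        capping = None
    else:
        capping = any(np.linalg.norm(d.coord - t.coord) <= hbond_cutoff
                      for d in donors for t in targets)
    return NcapMotif(ncap_residue=ncap_res, ncap_class=ncap_class,
                     capping_hbond=capping, preceding_residue=pre,
                     preceding_class=pre_class)


def annotate_pas(chain: Chain,
                 assignment: SSAssignment | None = None) -> PasAnnotation:
    """Recognise and label the PAS fold in a chain.

    ``is_pas`` requires exactly one five-strand sheet in the canonical
    2-5-1-4-3 spatial order (orientation-normalized) plus at least three
    helices, with a long (≥10 residue) helix N-terminal of β1 to serve as
    α1.  Failure to meet the pattern yields ``is_pas=False`` with a reason,
    not an error.
    """
    assignment = assignment or assign_secondary_structure(chain)
    elements = segment_elements(assignment, chain)
    helices = [e for e in elements if e.kind == "helix"]
    strands = [e for e in elements if e.kind == "strand"]

    ann = PasAnnotation(is_pas=False)
    ann.beta = {f"β{s.sequence_index}": s for s in strands}
    if len(strands) != 5:
        ann.reason = f"{len(strands)} strands (need 5)"
        return ann
    if len(helices) < 3:
        ann.reason = f"{len(helices)} helices (need ≥3)"
        return ann
    try:
        order = order_sheet_strands(strands, hbonds=assignment.hbonds)
    except SheetTopologyError as exc:
        ann.reason = str(exc)
        return ann
    ann.sheet_order = order
    if order != normalize_sheet_order(CANONICAL_ORDER):
        ann.reason = f"sheet order {order} is not canonical"
        return ann

    residues = chain.polymer_residues()
    pos = {id(r): i for i, r in enumerate(residues)}
    beta1 = strands[0]
    beta3 = strands[2]
    b1_start = pos[id(beta1.residues[0])]
    b1_end = pos[id(beta1.residues[-1])]
    b3_start = pos[id(beta3.residues[0])]

    n_term = [h for h in helices
              if pos[id(h.residues[-1])] < b1_start and len(h.residues) >= 10]
    if not n_term:
        ann.reason = "no long helix N-terminal of β1"
        return ann
    alpha1 = max(n_term, key=lambda h: len(h.residues))
    between = [h for h in helices
               if pos[id(h.residues[0])] > b1_end
               and pos[id(h.residues[-1])] < b3_start
               and h is not alpha1]
    if len(between) < 2:
        ann.reason = "fewer than two helices between β1 and β3"
        return ann
    alpha2, alpha3 = between[0], between[1]

    ann.is_pas = True
    ann.alpha = {"α1": alpha1, "α2": alpha2, "α3": alpha3}
    ann.ncap = detect_ncap(chain, alpha1)
    return ann
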