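"""Dimer-orientation classification for pairs of PAS-annotated chains.

For each pair of chains in contact the classifier decides (i) whether the
two monomers point the same way (parallel, by the directed angle between
their reference axes — the α1 helix axis when present) and (ii) which
canonical element forms the interface on each chain, defined as the
element with the largest solvent-accessible area buried on complex
formation.  A parallel dimer whose interface is α3 on both chains is the
non-canonical arrangement; α1 on both chains is the classic sensor-kinase
arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import AxisFit, angle_between, fit_axis
from .pas import PasAnnotation, annotate_pas
from .sasa import buried_fraction
from .structures import Chain, Structure, read_structure

__all__ = [
    "ClassifierParams",
    "DimerClassification",
    "find_chain_pairs",
    "classify_dimer",
    "screen_collection",
]

CLASS_ALPHA1 = "alpha1_interface"
CLASS_ALPHA3 = "alpha3_interface"
CLASS_OTHER = "other_interface"
CLASS_NOT_DIMER = "not_dimer"


@dataclass
class ClassifierParams:
    contact_cutoff: float = 5.0      # Å, heavy-atom contact distance
    min_contacts: int = 10           # pairs below cutoff to call chains "nearby"
    parallel_threshold: float = 45.0  # degrees, directed inter-axis angle
    probe: float = 1.4
    n_points: int = 960              # SASA sampling


@dataclass
class DimerClassification:
    chain_pair: tuple[str, str]
    n_contacts: int
    parallel: bool | None
    inter_axis_angle: float | None
    interface_element_A: str
    interface_element_B: str
    buried_area_by_element: dict[str, dict[str, float]] = field(default_factory=dict)
    class_label: str = CLASS_OTHER
    reason: str = ""


def _heavy_coords(chain: Chain) -> np.ndarray:
    rows = [a.coord for r in chain.polymer_residues()
            for a in r.atoms if a.element != "H"]
    return np.array(rows).reshape(-1, 3)


def _contact_count(chainA: Chain, chainB: Chain, cutoff: float) -> int:
    ca = _heavy_coords(chainA)
    cb = _heavy_coords(chainB)
    if ca.size == 0 or cb.size == 0:
        return 0
    tree = cKDTree(cb)
    return int(sum(len(hits) for hits in tree.query_ball_point(ca, cutoff)))


def find_chain_pairs(s: Structure, contact_cutoff: float = 5.0,
                     min_contacts: int = 10) -> list[tuple[str, str, int]]:
    """Unordered chain pairs with ≥ ``min_contacts`` heavy-atom contacts
    within ``contact_cutoff`` Å, as (id_A, id_B, n_contacts)."""
    out = []
    for i in range(len(s.chains)):
        for j in range(i + 1, len(s.chains)):
            n = _contact_count(s.chains[i], s.chains[j], contact_cutoff)
            if n >= min_contacts:
                out.append((s.chains[i].chain_id, s.chains[j].chain_id, n))
    return out


def _reference_axis(chain: Chain, pas: PasAnnotation) -> AxisFit:
    if pas.is_pas and "α1" in pas.alpha:
        return pas.alpha["α1"].axis
    ca = chain.ca_coords()
    return fit_axis(ca)


def _element_burial(chain: Chain, other: Chain, pas: PasAnnotation,
                    s: Structure, params: ClassifierParams) -> dict[str, float]:
    groupA = [(chain, r) for r in chain.polymer_residues()]
    groupB = [(other, r) for r in other.polymer_residues()]
    _, per_res = buried_fraction(s, groupA, groupB,
                                 probe=params.probe, n_points=params.n_points)
    burial: dict[str, float] = {}
    for label, element in list(pas.alpha.items()) + list(pas.beta.items()):
        total = sum(per_res.get((chain.chain_id, r.author_number, r.insertion_code), 0.0)
                    for r in element.residues)
        burial[label] = total
    return burial


def classify_dimer(s: Structure, pair: tuple[str, str],
                   pasA: PasAnnotation, pasB: PasAnnotation,
                   params: ClassifierParams | None = None) -> DimerClassification:
    """Classify the orientation of one chain pair.

    Pairs below the contact threshold are ``not_dimer``.  Chains that are
    not both PAS-annotated can only yield ``other_interface``.
    """
    params = params or ClassifierParams()
    chainA = s.chain(pair[0])
    chainB = s.chain(pair[1])
    n_contacts = _contact_count(chainA, chainB, params.contact_cutoff)
    if n_contacts < params.min_contacts:
        return DimerClassification(chain_pair=pair, n_contacts=n_contacts,
                                   parallel=None, inter_axis_angle=None,
                                   interface_element_A="none",
                                   interface_element_B="none",
                                   class_label=CLASS_NOT_DIMER,
                                   reason="below contact threshold")
    axisA = _reference_axis(chainA, pasA)
    axisB = _reference_axis(chainB, pasB)
    angle = angle_between(axisA, axisB, directed=True)
    parallel = angle < params.parallel_threshold

    if not (pasA.is_pas and pasB.is_pas):
        return DimerClassification(chain_pair=pair, n_contacts=n_contacts,
                                   parallel=parallel, inter_axis_angle=angle,
                                   interface_element_A="none",
                                   interface_element_B="none",
                                   class_label=CLASS_OTHER,
                                   reason="chain(s) not PAS-annotated")

    burialA = _element_burial(chainA, chainB, pasA, s, params)
    burialB = _element_burial(chainB, chainA, pasB, s, params)
    elemA = max(burialA, key=burialA.get) if burialA else "none"
    elemB = max(burialB, key=burialB.get) if burialB else "none"

    if parallel and elemA == elemB == "α3":
        label = CLASS_ALPHA3
    elif parallel and elemA == elemB == "α1":
        label = CLASS_ALPHA1
    else:
        label = CLASS_OTHER
    return DimerClassification(chain_pair=pair, n_contacts=n_contacts,
                               parallel=parallel, inter_axis_angle=angle,
                               interface_element_A=elemA,
                               interface_element_B=elemB,
                               buried_area_by_element={"A": burialA, "B": burialB},
                               class_label=label)


def screen_collection(paths: list[str | Path],
                      params: ClassifierParams | None = None,
                      ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every nearby chain pair in every structure file.

    Returns a table (one row per evaluated pair; files without pairs or
    with read errors produce a status row) and a per-class summary count.
    """
    params = params or ClassifierParams()
    rows = []
    summary: dict[str, int] = {}
    for path in paths:
        path = Path(path)
        try:
            s = read_structure(path)
        except Exception as exc:  # per-file failures must not abort the screen
            rows.append({"file": path.name, "chain_a": "", "chain_b": "",
                         "n_contacts": 0, "angle": np.nan,
                         "interface_a": "", "interface_b": "",
                         "class": "", "status": f"error: {exc}"})
            continue
        annotations = {ch.chain_id: annotate_pas(ch) for ch in s.chains}
        pairs = find_chain_pairs(s, params.contact_cutoff, params.min_contacts)
        if not pairs:
            rows.append({"file": path.name, "chain_a": "", "chain_b": "",
                         "n_contacts": 0, "angle": np.nan,
                         "interface_a": "", "interface_b": "",
                         "class": "", "status": "no chain pairs"})
            continue
        for ca_id, cb_id, _ in pairs:
            cls = classify_dimer(s, (ca_id, cb_id),
                                 annotations[ca_id], annotations[cb_id], params)
            rows.append({"file": path.name, "chain_a": ca_id, "chain_b": cb_id,
                         "n_contacts": cls.n_contacts,
                         "angle": (np.nan if cls.inter_axis_angle is None
                                   else round(cls.inter_axis_angle, 2)),
                         "interface_a": cls.interface_element_A,
                         "interface_b": cls.interface_element_B,
                         "class": cls.class_label, "status": "ok"})
            summary[cls.class_label] = summary.get(cls.class_label, 0) + 1
    table = pd.DataFrame(rows, columns=["file", "chain_a", "chain_b", "n_contacts",
                                        "angle", "interface_a", "interface_b",
                                        "class", "status"])
    return table, summary
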