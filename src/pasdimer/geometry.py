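"""Rigid-body mathematics: Kabsch superposition, iterative sequence-independent
structural alignment with outlier rejection, axis fitting, inter-axis angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import Chain, Residue

__all__ = [
    "SuperpositionResult",
    "AxisFit",
    "AlignmentError",
    "kabsch_superpose",
    "structure_align",
    "fit_axis",
    "angle_between",
    "apply_transform",
]


class AlignmentError(RuntimeError):
    pass


@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # 3x3, det +1
    translation: np.ndarray    # 3-vector, Å
    rmsd: float                # Å
    n_aligned: int
    correspondence: list[tuple] = field(default_factory=list)
    unique: bool = True        # False when the optimum rotation is degenerate

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class AxisFit:
    direction: np.ndarray   # unit 3-vector, N→C sign
    centroid: np.ndarray    # Å
    length: float           # Å, extent of points along the axis
    linearity: float        # variance explained by the first principal direction

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            self.direction = self.direction / n


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ np.asarray(rotation).T + np.asarray(translation)


def kabsch_superpose(P: np.ndarray, Q: np.ndarray,
                     correspondence: list[tuple] | None = None) -> SuperpositionResult:
    """Optimal proper rigid motion (R, t) minimizing RMSD(P, R·Q + t).

    Uses the SVD solution with the determinant sign correction so that the
    returned rotation is always proper.  The result is flagged non-unique
    when the point sets are (near-)collinear.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching n×3 arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    diff = P - (Q @ R.T + t)
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    # degenerate (collinear) input: the two smallest singular values of the
    # centered coordinates vanish, leaving the rotation about the line free
    sing = np.linalg.svd(P - cp, compute_uv=False)
    unique = bool(sing[1] > 1e-8 * max(sing[0], 1.0))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_aligned=n,
                               correspondence=list(correspondence or []),
                               unique=unique)


def fit_axis(coords: np.ndarray) -> AxisFit:
    """First principal axis of a run of CA coordinates, signed N→C."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be m×3")
    m = coords.shape[0]
    if m < 4:
        raise ValueError(f"axis fit needs ≥4 points, got {m}")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, coords[-1] - coords[0]) < 0:
        direction = -direction
    proj = centered @ direction
    total = float((s ** 2).sum())
    linearity = float(s[0] ** 2 / total) if total > 0 else 1.0
    return AxisFit(direction=direction, centroid=centroid,
                   length=float(proj.max() - proj.min()), linearity=linearity)


def angle_between(a: AxisFit, b: AxisFit, directed: bool = True) -> float:
    """Angle between two fitted axes in degrees.

    ``directed=True`` honours the N→C sign (range [0, 180]); otherwise the
    angle is folded into [0, 90].
    """
    cosang = float(np.clip(np.dot(a.direction, b.direction), -1.0, 1.0))
    ang = float(np.degrees(np.arccos(cosang)))
    if not directed:
        ang = min(ang, 180.0 - ang)
    return ang


def _ca_table(chain: Chain) -> tuple[list[Residue], np.ndarray]:
    residues = [r for r in chain.polymer_residues() if r.atom("CA") is not None]
    coords = np.array([r.atom("CA").coord for r in residues]).reshape(-1, 3)
    return residues, coords


def _seed_pairs(chainA: Chain, chainB: Chain) -> list[tuple[int, int]]:
    """Seed correspondence by matching same-kind secondary-structure elements
    in sequence order and pairing residues positionally within each match."""
    from .secondary import assign_secondary_structure, segment_elements

    pairs: list[tuple[int, int]] = []
    resA, _ = _ca_table(chainA)
    resB, _ = _ca_table(chainB)
    idxA = {id(r): i for i, r in enumerate(resA)}
    idxB = {id(r): i for i, r in enumerate(resB)}
    elemsA = segment_elements(assign_secondary_structure(chainA), chainA)
    elemsB = segment_elements(assign_secondary_structure(chainB), chainB)
    for kind in ("helix", "strand"):
        ka = [e for e in elemsA if e.kind == kind]
        kb = [e for e in elemsB if e.kind == kind]
        for ea, eb in zip(ka, kb):
            for ra, rb in zip(ea.residues, eb.residues):
                if id(ra) in idxA and id(rb) in idxB:
                    pairs.append((idxA[id(ra)], idxB[id(rb)]))
    if len(pairs) < 3:
        # featureless chains: fall back to positional pairing
        n = min(len(resA), len(resB))
        pairs = [(i, i) for i in range(n)]
    return pairs


def structure_align(chainA: Chain, chainB: Chain,
                    pair_cutoff: float = 5.0,
                    reject_cutoff: float = 3.5,
                    max_iter: int = 50) -> SuperpositionResult:
    """Sequence-independent CA alignment with iterative outlier rejection.

    Seeds a correspondence from matched secondary-structure elements, then
    iterates: Kabsch on the current pairs → re-pair mutually nearest CA
    atoms within ``pair_cutoff`` → drop pairs farther than ``reject_cutoff``
    — until the pair set is stable.  The reported RMSD is the Kabsch RMSD
    recomputed on the final correspondence.
    """
    resA, coordsA = _ca_table(chainA)
    resB, coordsB = _ca_table(chainB)
    if len(resA) < 20 or len(resB) < 20:
        raise AlignmentError("structure_align needs chains with ≥20 CA atoms")
    pairs = _seed_pairs(chainA, chainB)
    if len(pairs) < 3:
        raise AlignmentError("no seed correspondence found")

    prev: set[tuple[int, int]] | None = None
    result = None
    for _ in range(max_iter):
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        result = kabsch_superpose(coordsA[ia], coordsB[ib])
        moved = result.transform(coordsB)
        # mutually nearest neighbours within pair_cutoff
        treeB = cKDTree(moved)
        dist_ab, nn_ab = treeB.query(coordsA, k=1)
        treeA = cKDTree(coordsA)
        _, nn_ba = treeA.query(moved, k=1)
        new_pairs = [(i, int(nn_ab[i])) for i in range(len(resA))
                     if dist_ab[i] <= pair_cutoff and nn_ba[nn_ab[i]] == i
                     and dist_ab[i] <= reject_cutoff]
        if len(new_pairs) < 3:
            break
        pairs_set = set(new_pairs)
        if pairs_set == prev:
            pairs = new_pairs
            break
        prev = pairs_set
        pairs = new_pairs

    ia = [p[0] for p in pairs]
    ib = [p[1] for p in pairs]
    final = kabsch_superpose(coordsA[ia], coordsB[ib])
    final.correspondence = [(resA[i], resB[j]) for i, j in pairs]
    final.n_aligned = len(pairs)
    return final
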