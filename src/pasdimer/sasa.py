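"""Solvent-accessible surface area, interface burial, crystal-contact burial.

SASA uses the rolling-probe point-sampling construction with a fixed,
deterministic spiral (golden-angle) point set, so results are exactly
reproducible for a given ``n_points``.  Crystal-contact burial expands the
asymmetric unit by the space-group operators plus lattice translations and
measures how much of a residue range's isolated-chain surface the lattice
neighbours occlude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import Atom, Chain, CrystalInfo, Residue, Structure

__all__ = [
    "VDW_RADII",
    "SasaResult",
    "SymmetryMate",
    "shrake_rupley",
    "buried_fraction",
    "expand_symmetry",
    "crystal_contact_burial",
    "spiral_points",
]

# Bondi-style van der Waals radii (Å); overridable per call.
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "H": 1.20, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "FE": 1.80, "ZN": 1.39, "MG": 1.73, "CA": 2.31,
    "NA": 2.27, "K": 2.75, "MN": 1.80, "CU": 1.40,
}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


@dataclass
class SasaResult:
    atom_areas: np.ndarray                  # Å² per atom, input order
    residue_areas: dict[tuple[str, int, str], float]  # (chain, resnum, icode) → Å²
    total: float
    probe_radius: float
    n_points: int


@dataclass
class SymmetryMate:
    operator_index: int
    lattice_translation: tuple[int, int, int]
    chains: list[Chain] = field(default_factory=list)


def spiral_points(n: int) -> np.ndarray:
    """Deterministic golden-angle spiral points on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / ((1.0 + np.sqrt(5.0)) / 2.0)
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _radii_for(atoms: list[tuple[object, object, Atom]],
               radii: dict[str, float]) -> np.ndarray:
    out = np.empty(len(atoms))
    for k, (_, _, atom) in enumerate(atoms):
        key = atom.element.upper()
        if key not in radii:
            raise ValueError(f"no van der Waals radius for element {atom.element!r} "
                             f"(atom {atom.name})")
        out[k] = radii[key]
    return out


def shrake_rupley(atoms: list[tuple[object, Residue, Atom]],
                  probe: float = DEFAULT_PROBE,
                  n_points: int = DEFAULT_N_POINTS,
                  radii: dict[str, float] | None = None) -> SasaResult:
    """Per-atom SASA for (chain, residue, atom) triples.

    Each atom's expanded sphere (r + probe) is sampled at ``n_points``
    spiral points; a point is exposed if it lies outside every neighbour's
    expanded sphere.  Area = exposed fraction × 4π(r+probe)².
    """
    if not atoms:
        raise ValueError("no atoms given")
    radii = radii or VDW_RADII
    coords = np.array([a.coord for _, _, a in atoms])
    r = _radii_for(atoms, radii) + probe
    sphere = spiral_points(n_points)
    tree = cKDTree(coords)
    max_r = float(r.max())
    areas = np.empty(len(atoms))
    neighbor_lists = tree.query_ball_point(coords, 2.0 * max_r)
    for k in range(len(atoms)):
        pts = coords[k] + r[k] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[k]:
            if j == k:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > r[j] ** 2
        areas[k] = exposed.mean() * 4.0 * np.pi * r[k] ** 2

    residue_areas: dict[tuple[str, int, str], float] = {}
    for k, (ch, res, _) in enumerate(atoms):
        chain_id = ch.chain_id if isinstance(ch, Chain) else str(ch)
        key = (chain_id, res.author_number, res.insertion_code)
        residue_areas[key] = residue_areas.get(key, 0.0) + areas[k]
    return SasaResult(atom_areas=areas, residue_areas=residue_areas,
                      total=float(areas.sum()), probe_radius=probe,
                      n_points=n_points)


def _atom_triples(chains: list[Chain]) -> list[tuple[Chain, Residue, Atom]]:
    triples = []
    for ch in chains:
        for res in ch.polymer_residues():
            for atom in res.atoms:
                if atom.element != "H":
                    triples.append((ch, res, atom))
    return triples


def buried_fraction(s: Structure,
                    groupA: list[tuple[Chain, Residue]],
                    groupB: list[tuple[Chain, Residue]],
                    probe: float = DEFAULT_PROBE,
                    n_points: int = DEFAULT_N_POINTS,
                    ) -> tuple[float, dict[tuple[str, int, str], float]]:
    """Fraction of group A's isolated SASA buried by the presence of group B.

    Returns (fraction, per-residue buried area in Å² for group A residues).
    """
    if not groupA or not groupB:
        raise ValueError("both groups must be nonempty")
    keysA = {(ch.chain_id, r.author_number, r.insertion_code) for ch, r in groupA}
    keysB = {(ch.chain_id, r.author_number, r.insertion_code) for ch, r in groupB}
    if keysA & keysB:
        raise ValueError("groups must be disjoint")

    def triples(group):
        return [(ch, r, a) for ch, r in group for a in r.atoms if a.element != "H"]

    alone = shrake_rupley(triples(groupA), probe=probe, n_points=n_points)
    combined = shrake_rupley(triples(groupA) + triples(groupB),
                             probe=probe, n_points=n_points)
    if alone.total <= 0:
        raise ValueError("group A has zero isolated SASA; burial undefined")
    per_res: dict[tuple[str, int, str], float] = {}
    for key, area in alone.residue_areas.items():
        per_res[key] = area - combined.residue_areas.get(key, 0.0)
    buried = alone.total - sum(combined.residue_areas.get(k, 0.0) for k in keysA)
    return buried / alone.total, per_res


def _transform_chain(chain: Chain, matrix: np.ndarray, shift: np.ndarray,
                     suffix: str) -> Chain:
    new_res = []
    for res in chain.residues:
        atoms = [Atom(name=a.name, element=a.element,
                      coord=matrix @ a.coord + shift,
                      occupancy=a.occupancy, b_factor=a.b_factor,
                      altloc=a.altloc) for a in res.atoms]
        new_res.append(Residue(author_number=res.author_number,
                               insertion_code=res.insertion_code,
                               res_name=res.res_name, atoms=atoms,
                               is_hetero=res.is_hetero))
    return Chain(chain_id=f"{chain.chain_id}{suffix}", residues=new_res)


def expand_symmetry(s: Structure, radius: float = 5.0) -> list[SymmetryMate]:
    """All symmetry-operator + lattice-translation copies with any atom within
    ``radius`` Å of the asymmetric unit (identity at the origin excluded)."""
    if s.crystal is None:
        raise ValueError("structure carries no crystal information")
    crystal: CrystalInfo = s.crystal
    M = crystal.orthogonalization_matrix()
    Minv = np.linalg.inv(M)
    au_coords = np.array([a.coord for _, _, a in s.all_atoms()])
    if au_coords.size == 0:
        raise ValueError("no atoms in the asymmetric unit")
    au_tree = cKDTree(au_coords)
    au_frac = au_coords @ Minv.T
    center_frac = au_frac.mean(axis=0)

    mates: list[SymmetryMate] = []
    for op_idx, (rot, tran) in enumerate(crystal.operators):
        moved_center = rot @ center_frac + tran
        base_shift = np.round(center_frac - moved_center).astype(int)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    n = base_shift + np.array([dx, dy, dz])
                    identity = (np.allclose(rot, np.eye(3))
                                and np.allclose(tran + n, 0.0))
                    if identity:
                        continue
                    # Cartesian map: x' = M (rot · Minv x + tran + n)
                    A = M @ rot @ Minv
                    b = M @ (tran + n)
                    moved = au_coords @ A.T + b
                    d, _ = au_tree.query(moved, k=1,
                                         distance_upper_bound=radius)
                    if not np.any(np.isfinite(d)):
                        continue
                    mate = SymmetryMate(
                        operator_index=op_idx,
                        lattice_translation=tuple(int(v) for v in n),
                        chains=[_transform_chain(ch, A, b, f"_{op_idx}_{dx}{dy}{dz}")
                                for ch in s.chains],
                    )
                    mates.append(mate)
    return mates


def crystal_contact_burial(s: Structure, chain_id: str,
                           residue_range: tuple[int, int] | None = None,
                           radius: float = 5.0,
                           probe: float = DEFAULT_PROBE,
                           n_points: int = DEFAULT_N_POINTS) -> float:
    """Fraction of a residue range's isolated-chain SASA buried by crystal
    contacts (other asymmetric-unit chains plus symmetry mates within
    ``radius``).  ``residue_range=None`` scores the whole chain."""
    chain = s.chain(chain_id)
    mates = expand_symmetry(s, radius=radius)
    env_chains = [ch for ch in s.chains if ch.chain_id != chain_id]
    for mate in mates:
        env_chains.extend(mate.chains)

    iso = shrake_rupley(_atom_triples([chain]), probe=probe, n_points=n_points)
    ctx = shrake_rupley(_atom_triples([chain] + env_chains),
                        probe=probe, n_points=n_points)

    def range_total(res: SasaResult) -> float:
        total = 0.0
        for (cid, num, _), area in res.residue_areas.items():
            if cid != chain.chain_id:
                continue
            if residue_range is not None and not (residue_range[0] <= num <= residue_range[1]):
                continue
            total += area
        return total

    iso_total = range_total(iso)
    if iso_total <= 0:
        raise ValueError("residue range has zero isolated SASA")
    ctx_total = 0.0
    for (cid, num, _), area in ctx.residue_areas.items():
        if cid != chain.chain_id:
            continue
        if residue_range is not None and not (residue_range[0] <= num <= residue_range[1]):
            continue
        ctx_total += area
    return (iso_total - ctx_total) / iso_total
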