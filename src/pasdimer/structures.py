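"""Macromolecular structure I/O and the coordinate hierarchy.

Structures are read with gemmi (PDB and mmCIF) into a small, explicit
hierarchy (:class:`Structure` → :class:`Chain` → :class:`Residue` →
:class:`Atom`) that carries exactly what the downstream geometry needs:
author residue numbering, occupancies, B-factors (which hold pLDDT for
predicted models), and crystal symmetry.  Alternate locations are reduced
to a single conformer at read time; hydrogens are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "CrystalInfo",
    "Structure",
    "DaliHit",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "extract_plddt_profile",
    "parse_dali_hits",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class StructureParseError(ValueError):
    """Raised when a coordinate or hit-list file cannot be interpreted."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    author_number: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    is_hetero: bool = False

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_NAMES)

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_NAMES]

    @property
    def label(self) -> str:
        return f"{self.res_name}{self.author_number}{self.insertion_code}"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def polymer_residues(self) -> list[Residue]:
        """Protein residues used by geometric analyses (no waters/ligands)."""
        return [r for r in self.residues
                if not r.is_hetero and r.res_name not in WATER_NAMES]

    def residue_by_number(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.author_number == number and r.insertion_code == icode:
                return r
        return None

    def ca_coords(self) -> np.ndarray:
        rows = [r.atom("CA").coord for r in self.polymer_residues() if r.atom("CA")]
        return np.array(rows, dtype=float).reshape(-1, 3)


@dataclass
class CrystalInfo:
    space_group: str
    cell: tuple[float, float, float, float, float, float]
    operators: list[tuple[np.ndarray, np.ndarray]]  # fractional (rot 3x3, trans 3)

    def __post_init__(self) -> None:
        ops = []
        has_identity = False
        for rot, tran in self.operators:
            rot = np.asarray(rot, dtype=float)
            tran = np.asarray(tran, dtype=float)
            det = np.linalg.det(rot)
            if abs(abs(det) - 1.0) > 1e-6:
                raise ValueError(f"symmetry rotation determinant {det}, expected ±1")
            if np.allclose(rot, np.eye(3)) and np.allclose(tran, 0.0):
                has_identity = True
            ops.append((rot, tran))
        if not has_identity:
            raise ValueError("identity operator missing from symmetry list")
        self.operators = ops

    def orthogonalization_matrix(self) -> np.ndarray:
        """Fractional → Cartesian matrix (standard PDB convention)."""
        a, b, c, alpha, beta, gamma = self.cell
        al, be, ga = np.radians([alpha, beta, gamma])
        v = np.sqrt(1 - np.cos(al) ** 2 - np.cos(be) ** 2 - np.cos(ga) ** 2
                    + 2 * np.cos(al) * np.cos(be) * np.cos(ga))
        return np.array([
            [a, b * np.cos(ga), c * np.cos(be)],
            [0.0, b * np.sin(ga), c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)],
            [0.0, 0.0, c * v / np.sin(ga)],
        ])


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    crystal: CrystalInfo | None = None
    source_format: str = "pdb"

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in structure {self.id}: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id}")

    def all_atoms(self, heavy_only: bool = True, polymer_only: bool = True):
        """Yield (chain, residue, atom) triples in file order."""
        for ch in self.chains:
            residues = ch.polymer_residues() if polymer_only else ch.residues
            for res in residues:
                for atom in res.atoms:
                    if heavy_only and atom.element == "H":
                        continue
                    yield ch, res, atom


@dataclass(frozen=True)
class DaliHit:
    pdb_chain_id: str
    z_score: float


def _select_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by alphabetically first altloc
    return min(atoms, key=lambda a: (-a.occ, a.altloc or ""))


def _convert_gemmi(st: gemmi.Structure, drop_hydrogens: bool = True) -> Structure:
    chains: list[Chain] = []
    model = st[0]
    for gch in model:
        residues: list[Residue] = []
        for gres in gch:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                if drop_hydrogens and ga.element.name in ("H", "D"):
                    continue
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, group in by_name.items():
                ga = _select_altloc(group)
                atoms.append(Atom(
                    name=name,
                    element=ga.element.name,
                    coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    b_factor=ga.b_iso,
                    altloc=ga.altloc or "",
                ))
            if not atoms:
                continue
            residues.append(Residue(
                author_number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                res_name=gres.name,
                atoms=atoms,
                is_hetero=(gres.het_flag == "H"),
            ))
        if residues:
            chains.append(Chain(chain_id=gch.name, residues=residues))

    crystal = None
    cell = st.cell
    if cell.a > 1.0 and st.spacegroup_hm:  # gemmi uses a=1 placeholder when absent
        sg = gemmi.SpaceGroup(st.spacegroup_hm)
        ops = []
        for op in sg.operations():
            rot = np.array(op.rot, dtype=float) / op.DEN
            tran = np.array(op.tran, dtype=float) / op.DEN
            ops.append((rot, tran))
        crystal = CrystalInfo(
            space_group=st.spacegroup_hm,
            cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
            operators=ops,
        )
    return Structure(id=st.name or "structure", chains=chains, crystal=crystal)


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the internal hierarchy.

    Alternate conformers are reduced to the highest-occupancy one (ties:
    alphabetically first altloc); hydrogens are discarded.  ``format`` is
    one of ``pdb``, ``mmcif`` or ``auto`` (sniff by extension/content).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if format not in fmt_map:
        raise ValueError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models found")
    out = _convert_gemmi(st)
    if not out.chains:
        raise StructureParseError(f"{path}: no atom records found")
    out.id = st.name or path.stem
    out.source_format = "mmcif" if (format == "mmcif" or path.suffix.lower() in (".cif", ".mmcif")) else "pdb"
    return out


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(s: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write a structure as PDB v3.3 text.

    Round-trips coordinates to 1e-3 Å (the PDB field precision) and author
    numbering exactly.
    """
    if format != "pdb":
        raise ValueError(f"unsupported output format {format!r}")
    if not s.chains or not any(c.residues for c in s.chains):
        raise ValueError("refusing to write an empty structure")
    lines: list[str] = []
    if s.crystal is not None:
        a, b, c, al, be, ga = s.crystal.cell
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} "
            f"{s.crystal.space_group:<11s}{1:4d}"
        )
    serial = 1
    for chain in s.chains:
        if len(chain.chain_id) > 1:
            raise ValueError(
                f"chain id {chain.chain_id!r} too long for the PDB dialect")
        for res in chain.residues:
            record = "HETATM" if res.is_hetero else "ATOM  "
            for atom in res.atoms:
                lines.append(
                    f"{record}{serial:5d} {_format_atom_name(atom.name, atom.element)}"
                    f"{atom.altloc or ' ':1s}{res.res_name:>3s} {chain.chain_id:1s}"
                    f"{res.author_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          "
                    f"{atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].res_name:>3s} "
                     f"{chain.chain_id:1s}{chain.residues[-1].author_number:4d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def extract_plddt_profile(s: Structure) -> tuple[list[tuple[str, int, float]], float]:
    """Per-residue pLDDT (CA B-factor) and its mean.

    Predicted-model files store pLDDT (0–100) in the B-factor column.  A
    warning is emitted when values fall outside [0, 100] (e.g. a crystal
    structure was passed); values are returned unclamped either way.
    """
    values: list[tuple[str, int, float]] = []
    for chain in s.chains:
        for res in chain.polymer_residues():
            ca = res.atom("CA")
            if ca is None:
                warnings.warn(f"residue {chain.chain_id}/{res.label} has no CA; skipped")
                continue
            values.append((chain.chain_id, res.author_number, ca.b_factor))
    if not values:
        raise ValueError("no CA atoms found; cannot build a pLDDT profile")
    arr = np.array([v[2] for v in values])
    if arr.min() < 0.0 or arr.max() > 100.0:
        warnings.warn("B-factor values outside [0, 100]; this may not be a "
                      "predicted model carrying pLDDT")
    return values, float(arr.mean())


def parse_dali_hits(path: str | Path, z_min: float = 2.0,
                    chain_col: int = 0, z_col: int = 1) -> list[DaliHit]:
    """Parse a plain-text Dali hit list, keeping hits with Z-score > ``z_min``.

    The threshold is a strict inequality.  The hit-list dialect varies by
    server version, so the whitespace-separated column holding the chain id
    and the one holding the Z-score are configurable.  Malformed lines are
    skipped with a warning.
    """
    hits: list[DaliHit] = []
    n_bad = 0
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        try:
            chain_id = tokens[chain_col]
            z = float(tokens[z_col])
        except (IndexError, ValueError):
            n_bad += 1
            continue
        if not np.isfinite(z):
            n_bad += 1
            continue
        if z > z_min:
            hits.append(DaliHit(pdb_chain_id=chain_id, z_score=z))
    if n_bad:
        warnings.warn(f"{n_bad} malformed line(s) skipped in {path}")
    return hits
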