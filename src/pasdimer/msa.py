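"""Multiple-sequence-alignment handling: redundancy filtering, column↔query
mapping, conservation profiling, and the helix N-cap sequence census.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO

from .pas import NCAP_RULES

__all__ = [
    "Msa",
    "ConservationProfile",
    "MotifCensus",
    "read_msa",
    "pairwise_identity",
    "remove_redundancy",
    "map_columns_to_query",
    "conservation_profile",
    "ncap_census",
]

GAP_CHARS = frozenset("-.")


def _is_gap(c: str) -> bool:
    return c in GAP_CHARS


@dataclass
class Msa:
    records: list[tuple[str, str]]     # (id, aligned sequence)
    query_id: str | None = None

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate record ids in alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def sequence(self, rec_id: str) -> str:
        for rid, seq in self.records:
            if rid == rec_id:
                return seq
        raise KeyError(rec_id)


@dataclass
class ConservationProfile:
    frequencies: list[dict[str, float]]   # per column, gap-excluded
    gap_fraction: list[float]
    score: list[float]                    # max non-gap frequency
    low_coverage: list[bool]              # gap fraction > 0.5
    query_numbers: list[int | None] | None = None


@dataclass
class MotifCensus:
    n_total: int
    n_capping_box: int
    n_non_traditional: int
    n_absent: int
    n_preceding_LI: int
    n_preceding_MV: int
    n_preceding_other: int
    n_unscored: int
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_total > 0 and not self.fractions:
            self.fractions = {
                "capping_box": self.n_capping_box / self.n_total,
                "non_traditional": self.n_non_traditional / self.n_total,
                "absent": self.n_absent / self.n_total,
                "preceding_LI": self.n_preceding_LI / self.n_total,
                "preceding_MV": self.n_preceding_MV / self.n_total,
                "preceding_other": self.n_preceding_other / self.n_total,
            }


def read_msa(path: str | Path, format: str = "fasta",
             query_id: str | None = None) -> Msa:
    """Read an aligned FASTA or Stockholm file (annotations ignored)."""
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise ValueError(f"cannot read alignment {path}: {exc}") from exc
    records = [(rec.id, str(rec.seq).upper()) for rec in aln]
    return Msa(records=records, query_id=query_id)


def pairwise_identity(a: str, b: str, mode: str = "any_nongap") -> float:
    """Percent identity between two aligned sequences.

    Denominator modes: ``any_nongap`` (columns where at least one sequence
    is non-gap; default), ``both_nongap``, ``shorter`` (ungapped length of
    the shorter sequence).
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    ident = sum(1 for x, y in zip(a, b)
                if x == y and not _is_gap(x))
    if mode == "any_nongap":
        denom = sum(1 for x, y in zip(a, b) if not (_is_gap(x) and _is_gap(y)))
    elif mode == "both_nongap":
        denom = sum(1 for x, y in zip(a, b) if not _is_gap(x) and not _is_gap(y))
    elif mode == "shorter":
        denom = min(sum(1 for x in a if not _is_gap(x)),
                    sum(1 for y in b if not _is_gap(y)))
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    if denom == 0:
        raise ValueError("no comparable columns between sequences")
    return 100.0 * ident / denom


def remove_redundancy(m: Msa, threshold: float,
                      mode: str = "any_nongap") -> Msa:
    """Greedy redundancy filter: keep a sequence only if its identity to every
    already-kept sequence is below ``threshold`` percent.

    Greedy order: query first (always retained), then descending ungapped
    length, ties by input order.  Idempotent, and the retained set is
    certified below threshold by construction.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")

    def ungapped_len(seq: str) -> int:
        return sum(1 for c in seq if not _is_gap(c))

    order = sorted(range(len(m.records)),
                   key=lambda i: (m.records[i][0] != m.query_id,
                                  -ungapped_len(m.records[i][1]), i))
    kept: list[int] = []
    for i in order:
        seq_i = m.records[i][1]
        is_query = m.records[i][0] == m.query_id
        if is_query or all(pairwise_identity(seq_i, m.records[j][1], mode=mode) < threshold
                           for j in kept):
            kept.append(i)
    kept.sort()
    return Msa(records=[m.records[i] for i in kept], query_id=m.query_id)


def map_columns_to_query(m: Msa, first_residue_number: int = 1
                         ) -> dict[int, int]:
    """Map alignment columns (0-based) to query residue numbers.

    Columns where the query row is gapped are absent from the mapping.
    """
    if m.query_id is None:
        raise ValueError("alignment has no query id")
    seq = m.sequence(m.query_id)
    if all(_is_gap(c) for c in seq):
        raise ValueError("query row is all gaps")
    mapping: dict[int, int] = {}
    num = first_residue_number
    for col, c in enumerate(seq):
        if not _is_gap(c):
            mapping[col] = num
            num += 1
    return mapping


def conservation_profile(m: Msa) -> ConservationProfile:
    """Per-column residue frequencies (gap-excluded), gap fraction, and a
    max-frequency conservation score; columns >50% gapped are flagged."""
    if len(m) < 2:
        raise ValueError("conservation needs ≥2 records")
    n = len(m)
    freqs, gapfrac, score, lowcov = [], [], [], []
    for col in range(m.n_columns):
        column = [seq[col] for _, seq in m.records]
        nongap = [c for c in column if not _is_gap(c)]
        counts = Counter(nongap)
        total = len(nongap)
        f = {aa: c / total for aa, c in counts.items()} if total else {}
        freqs.append(f)
        gapfrac.append(1.0 - total / n)
        score.append(max(f.values()) if f else 0.0)
        lowcov.append(gapfrac[-1] > 0.5)
    query_numbers = None
    if m.query_id is not None:
        mapping = map_columns_to_query(m)
        query_numbers = [mapping.get(col) for col in range(m.n_columns)]
    return ConservationProfile(frequencies=freqs, gap_fraction=gapfrac,
                               score=score, low_coverage=lowcov,
                               query_numbers=query_numbers)


def ncap_census(m: Msa, ncap_column: int, preceding_column: int,
                rules: dict[str, frozenset] | None = None) -> MotifCensus:
    """Count N-cap motif categories at a query-anchored alignment column.

    Records gapped at ``ncap_column`` are tallied as unscored; fractions are
    over the scored records.  Preceding-residue classes (branched
    hydrophobes) are read at ``preceding_column`` of the same records.
    """
    rules = rules or NCAP_RULES
    if not (0 <= ncap_column < m.n_columns and 0 <= preceding_column < m.n_columns):
        raise IndexError("census column out of range")
    n_cap = n_nt = n_abs = n_li = n_mv = n_other = n_unscored = 0
    for _, seq in m.records:
        c = seq[ncap_column]
        if _is_gap(c):
            n_unscored += 1
            continue
        if c in rules["capping_box"]:
            n_cap += 1
        elif c in rules["non_traditional"]:
            n_nt += 1
        else:
            n_abs += 1
        p = seq[preceding_column]
        if p in rules["preceding_LI"]:
            n_li += 1
        elif p in rules["preceding_MV"]:
            n_mv += 1
        else:
            n_other += 1
    n_total = len(m.records) - n_unscored
    return MotifCensus(n_total=n_total, n_capping_box=n_cap,
                       n_non_traditional=n_nt, n_absent=n_abs,
                       n_preceding_LI=n_li, n_preceding_MV=n_mv,
                       n_preceding_other=n_other, n_unscored=n_unscored)
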