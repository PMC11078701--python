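# Methods

This note records the models, conventions and numerical choices behind
`pasdimer`, and what the synthetic test surface does and does not
demonstrate about real data.

## Coordinate model

Structures are reduced at read time to a single-conformer, hydrogen-free
hierarchy. Alternate locations keep the highest-occupancy conformer (ties:
alphabetically first altloc), because all downstream geometry assumes one
position per atom. Waters and non-polymer heteroatoms are carried in the
hierarchy but excluded from geometric analyses (`polymer_residues()`), as
the analyses here are protein-only. Author residue numbering is preserved
verbatim so residues can be addressed exactly as deposited (e.g. N107,
M33–A79); internal 0-based indices are never exposed. Dali hit lists are
parsed with configurable column positions because the server's text format
varies by version; the Z-score threshold is a strict `>` comparison.

## Secondary structure

Assignment uses the Kabsch–Sander electrostatic hydrogen-bond model with
the standard −0.5 kcal/mol cutoff, reduced to three states (all helix
classes → H, bridges/ladders → E, else C); only three states are needed by
the downstream fold logic. Amide hydrogens are reconstructed at 1.0 Å from
N, in the C(prev)–N–CA plane opposite the bisector of the two bonds — a
geometric stand-in adequate for the energy model; the first residue of a
chain falls back to the N→CA opposite direction, and prolines never
donate. Helices require two consecutive n-turns (n = 3, 4, 5); strands are
residues in parallel or antiparallel bridges. Minimum element lengths are
4 (helix) and 3 (strand), standard conventions; a 3-residue 3₁₀ bridge
element would therefore not be emitted as a helix element, a deliberate
trade-off noted here because short single-turn helices do occur at
PAS–transmembrane linkers.

Energies are clamped at −9.9 kcal/mol and undefined when backbone atoms
are missing. Bond search is restricted to residue pairs with Cα closer
than 9 Å, which is conservative for this energy model.

## PAS-fold recognition

A chain is annotated as a PAS domain when its strands form exactly one
five-stranded sheet whose spatial order of sequence indices is the
canonical 2-5-1-4-3 (orientation-normalized: a sheet-order string and its
reversal are the same topology), with at least three helices. Sheet
adjacency requires a mean nearest-Cα distance < 5.5 Å and ≥2 inter-strand
backbone hydrogen bonds; the sheet must form a single unbranched path
(branched adjacency = fused sheet or barrel, out of scope). Canonical
labels follow the extracytoplasmic-sensor convention: α1 is the longest
helix (≥10 residues) wholly N-terminal of β1 — the "periplasmic" helix —
and α2, α3 are the next two helices between β1 and β3.

The α1 N-cap is scored two ways. Sequence tier: the residue immediately
preceding the first helical residue (N′) is a capping box if S/T/N/D, a
non-traditional cap if G/P/E/Q/H, else absent; the residue before that
(N″) is classed L/I, M/V, or other. The non-traditional set is an explicit
package choice — published N-cap censuses do not agree on a single rule
table — so census fractions at the category boundary depend on it.
Structural tier: a capping hydrogen bond is called when a side-chain O/N
of N′ or N1 lies within 3.5 Å of the backbone N of N2/N3; it is reported
as undetermined (never true) when the partner atoms are absent.

## Dimer-orientation classification

Chains are "nearby" when ≥10 heavy-atom pairs fall within 5.0 Å; both
values are configuration-exposed because any such cutoff is a convention.
The pair is parallel when the directed angle between chain reference axes
(the α1 helix axis when present, else the first principal axis of the Cα
set, signed N→C) is below 45°. The interface element per chain is the
canonical element with the largest buried solvent-accessible area
(isolated-chain SASA minus in-complex SASA summed over element residues);
burial is the standard quantitative definition of an interface and makes
"facing each other" measurable. A parallel pair with α3 the top-buried
element on both chains is `alpha3_interface`; α1 on both chains,
`alpha1_interface`; anything else `other_interface`; below the contact
threshold, `not_dimer`. Chains that fail PAS annotation are still
screened but can only yield `other_interface`, since a heterogeneous
structure collection contains many non-PAS neighbours.

## SASA and crystal contacts

Shrake–Rupley areas use a deterministic golden-angle spiral point set
(default 960 points, probe 1.4 Å) over Bondi-type van der Waals radii
(overridable per call); determinism matters because screen outputs are
compared byte-for-byte. Doubling the point count changes a single-sphere
area by <0.5 %. Crystal-contact burial expands the asymmetric unit by all
space-group operators and lattice translations with any atom within 5.0 Å
(default), then measures the fraction of a residue range's isolated-chain
SASA occluded by all neighbours simultaneously. Both the residue-range and
the whole-chain readings are available (`residue_range=None`), since
"burial of a region" can reasonably mean either.

## MSA handling

Pairwise identity defaults to identities over columns where at least one
sequence is non-gap; both-non-gap and shorter-sequence denominators are
selectable because alignment viewers differ on this convention. Redundancy
filtering is greedy — query first (always retained), then descending
ungapped length, ties by input order; keep a sequence only if its identity
to every kept sequence is below threshold. The procedure is idempotent and
the retained set is certified below threshold by full recomputation in the
tests. Absolute filtered counts from real searches depend on the database
snapshot and are not reproducible quantities. Conservation is scored as
the per-column maximum non-gap frequency (an entropy variant would change
ranking only at near-uniform columns); columns >50 % gapped are flagged.
The N-cap census takes explicit column arguments because which alignment
column "is" the N-cap position across homologs is itself an analysis
choice; records gapped at the scored column are tallied separately.

## Synthetic data generator

The generator emulates the inputs the analyses consume, with ground truth
attached by construction:

- **Backbones** are grown by internal-coordinate (NeRF) extension from
  standard bond lengths and angles, ω = 180°, helices at φ/ψ = −57/−47 and
  strands at −139/135. Side chains are limited to CB everywhere plus the
  N-cap serine OG (ideal staggered rotamer) — the single structural
  check that needs a side chain.
- **Sheets**: a template strand is placed at 4.8 Å slot spacing in the
  spatial order 2-5-1-4-3 (slots alternate direction, so the sheet is
  antiparallel); each new strand's roll and axial register are
  grid-searched to maximize the number of interior bridge residues to its
  neighbour under the same hydrogen-bond model the assignment uses. Edge
  residues are excluded from the search objective because their amide
  geometry changes when connector loops attach.
- **α1 block**: Gly-Leu-Ser precede the helix; the serine's φ/ψ are
  grid-searched so that its carbonyl accepts the first helical turn
  (making it the N′ residue) and its OG caps the backbone N of the second
  or third helical residue at ≈3 Å — the classic capping-box geometry.
- **Loops** are straight geometric connectors (Gly backbones bulged away
  from the fold); their chemistry is deliberately ignored.
- **Dimers** place a second copy by an exact two-fold rotation: about a
  z-parallel axis for parallel dimers (preserves the N→C helix direction)
  or a y-parallel axis for antiparallel ones. The axis position is found
  by bisection so the minimum inter-chain heavy-atom distance equals the
  requested separation (±0.3 Å); separations below 2.5 Å are rejected as
  clashes. Interface helices are rolled to present their flattest face to
  the partner, since real interfaces pack faces rather than single side-
  chain knobs. The validation grid uses separations 3.0/3.4/3.8 Å —
  the van-der-Waals-contact range typical of packed protein interfaces —
  plus 30 Å for the monotone flip to `not_dimer`.
- **MSAs** mutate a random seed sequence at a rate set so the mean
  pairwise identity hits the target (±2 %); motif columns are excluded
  from mutation and planted at exact counts by largest-remainder rounding,
  so a 0.9 capping-box frequency over 100 records is exactly 90.

Ground-truth element ranges are the constructed blocks; the assignment is
expected to recover each element *within* its block (DSSP-style labelling
trims one residue at element ends by construction of the turn/bridge
definitions), mapped one-to-one onto the canonical labels.

**What the fixtures do not show.** Ideal geometry has none of the
curvature, twist, irregular loops, side-chain packing or experimental
noise of real structures. Passing the fixture grid demonstrates that the
decision logic (orientation test, burial argmax, sheet-topology walk,
census arithmetic) is correct under unambiguous inputs with dominant
burial margins; it does not measure robustness to borderline real
interfaces, which is governed by the exposed thresholds.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; SASA point sets, grid
searches and bisections are deterministic, so identical inputs and
configuration give byte-identical screen outputs. The validation grid
(2 interface elements × 2 orientations × 3 separations × 3 global
rotations, plus the far-separation point) and SASA sampling at 240 points
for the screen (960 for the sphere oracles) keep the full validation run
to about two minutes on one CPU; classification depends only on the argmax
of per-element burial, which is insensitive to the point count at these
margins.

## Known limitations

- The structural-alignment seed matches same-kind elements in sequence
  order; domains with permuted element order would need the slower
  all-pairs seeding this package does not implement.
- Sheet-order computation assumes a linear sheet; β-barrels and fused
  sheets raise a topology error by design.
- The N-cap category rules are one defensible table among several; census
  fractions near category boundaries shift with the table.
- Crystal-contact burial treats all lattice neighbours within the mate
  radius simultaneously; no attempt is made to rank individual contacts
  or judge their physiological relevance.
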