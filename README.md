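# pasdimer

Structural-bioinformatics toolkit for analysing the periplasmic **PAS
sensor domains of bacterial histidine kinases** — in particular for asking,
across a collection of crystal structures and predicted models, *which
secondary-structure element forms the dimer interface*.

Sensor kinases such as PhoQ, CitA and DcuS dimerize through the long
N-terminal "periplasmic" helix (α1) of their extracytoplasmic PAS domain.
A second, non-canonical arrangement places the **α3 helix** of the PAS fold
at the interface instead, with the two monomers parallel and their α1
helices facing outward. Distinguishing these two orientations — and the
sequence signature that travels with the second one, an N-cap motif at the
start of α1 — is the analysis this package automates.

## What it does

- **Structure I/O** (`pasdimer.structures`): PDB/mmCIF reading (gemmi),
  PDB writing, crystal symmetry operators, pLDDT profiles from predicted
  models (B-factor column), Dali hit-list parsing with a strict Z-score
  threshold.
- **Rigid-body geometry** (`pasdimer.geometry`): Kabsch superposition,
  sequence-independent Cα alignment with iterative outlier rejection, axis
  fitting, inter-axis angles.
- **Secondary structure** (`pasdimer.secondary`): three-state (H/E/C)
  assignment from the Kabsch–Sander backbone hydrogen-bond energy
  `E = 0.084·332·(1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN)` kcal/mol, element
  segmentation, polar-contact detection.
- **PAS annotation** (`pasdimer.pas`): recognises the fold (five-stranded
  antiparallel sheet in the canonical **2-5-1-4-3** spatial order plus ≥3
  helices), labels α1/α2/α3 and β1–β5, and classifies the α1 N-cap
  (capping-box vs non-traditional motifs; Leu/Ile vs Met/Val at the
  position before the cap).
- **Dimer classification** (`pasdimer.dimer`): for every pair of chains in
  contact, decides parallel vs antiparallel (directed angle between α1
  axes) and assigns the interface element per chain as the element with
  the largest buried solvent-accessible area — yielding
  `alpha1_interface`, `alpha3_interface`, `other_interface` or `not_dimer`.
- **SASA** (`pasdimer.sasa`): deterministic Shrake–Rupley areas (spiral
  point sets), interface burial fractions, symmetry expansion and
  crystal-contact burial of residue ranges.
- **MSA tools** (`pasdimer.msa`): aligned FASTA/Stockholm input, pairwise
  identity, greedy redundancy filtering certified below threshold,
  column↔query mapping, conservation profiles, and the N-cap sequence
  census over homolog alignments.
- **Synthetic fixtures** (`pasdimer.fixtures`): ideal-geometry PAS
  monomers, dimers of chosen interface/orientation/separation, and MSAs
  with exactly planted motif frequencies — every generator output carries
  its ground truth.

## Worked example

Generate a labelled α3-interface dimer, screen it next to a classic
α1-interface dimer, and inspect the verdicts:

```bash
mkdir structs
pasdimer fixtures --kind pas_dimer --interface a3 --parallel --sep 3.8 \
    --seed 17 --out structs/d3.pdb --truth d3.json
pasdimer fixtures --kind pas_dimer --interface a1 --parallel --sep 3.8 \
    --seed 17 --out structs/d1.pdb
pasdimer screen structs --out screen.tsv --summary screen.json
```

prints

```
{"alpha1_interface": 1, "alpha3_interface": 1}
```

i.e. one chain pair was classified per file, one in each orientation class.
`screen.tsv` holds the per-pair evidence (contact count, inter-axis angle,
interface element on each chain). Superposing one fixture chain onto a
rigidly moved copy of itself:

```bash
pasdimer compare structs/d3.pdb:A structs/d1.pdb:B
```

```
rmsd    n_aligned       identity_pct
0.001   102     100.0
```

— 102 Cα atoms aligned at 0.001 Å RMSD and 100 % sequence identity, as
expected for two copies of the same synthetic monomer. The N-cap census on
a synthetic 100-sequence alignment with a planted 90 % capping-box
frequency:

```bash
pasdimer fixtures --kind msa --seed 3 --out m.fasta
pasdimer msa ncap m.fasta --ncap-col 40 --pre-col 38
```

```
category        count   fraction
capping_box     90      0.9000
non_traditional 8       0.0800
absent          2       0.0200
```

The same census applied to a real homolog alignment (query-anchored at the
α1 N-cap column) reports the fraction of homologs carrying the motif.

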