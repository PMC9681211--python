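# mabstitch

Construction, regularization and auditing of an all-atom model of a whole
IgG1 monoclonal antibody from its fragment structures.

Whole antibodies resist crystallography because the hinge is flexible, so
high-resolution structures exist mainly for the fragments: the two
antigen-binding Fabs and the glycosylated Fc. `mabstitch` implements the
grafting route to a complete model of the NIST monoclonal antibody reference
material (an IgG1κ, 1326 amino acids in four chains: heavy H/V of 450
residues, light L/M of 213): two Fab copies, one Fc and a donor hinge —
including the paired Cys-Pro-Pro-Cys (CPPC) core with both inter-chain
disulfides intact — are spliced into one structure, mutated to the target
sequence, completed (pyroglutamate N-termini, missing C-terminal residues,
G1F/G0F N-glycans at Asn300, hydrogens), relieved of grafting strain by
staged minimization, and placed in a canonical reference frame.

The package is organised as a library (`src/mabstitch`) driven by numbered
analysis scripts (`analysis/`) and a CLI (`mabstitch`), with every input a
synthetic fixture so the whole suite runs offline.

## The bookkeeping at the core

For a chain of *n* residues the elemental composition is computed by
condensation bookkeeping over free monomers:

```
composition = Σ monomer − (n−1)·H₂O − NH₃·[pyroglutamate]
              − 1 H per disulfide half-cystine − 1 H per N-glycosylation site
```

with ionizable side chains at physiological charge (Lys/Arg +1 H, Asp/Glu
−1 H, His with a single ring NH) and neutral termini. An N-glycosidic bond
is split between its sides: the Asn chain loses one amide hydrogen, the
glycan loses the anomeric hydroxyl; glycosidic bonds inside a glycan cost
the glycan one water each. The Fc glycans are canonical biantennary trees:
G0F = 4 GlcNAc + 3 hexose + fucose (8 sugars), G1F adds one terminal
galactose (9 sugars).

Geometry rests on Kabsch superposition (proper rotations only), ideal
residue templates from the Chemical Component Dictionary, a surrogate
potential (harmonic bonds and angles, soft-sphere repulsion with 1-2/1-3
exclusions) minimized by 500 steepest-descent + 500 conjugate-gradient
steps, and a two-fold (dyad) axis extracted from the rotation relating the
two Fc heavy-chain copies. Minimal covalent rings through the two hinge
disulfides are found exactly by unit-capacity min-cost flow on the bond
graph.

## Worked example

```
$ python analysis/03_hinge_ring.py
paired-CPPC covalent ring: 28 atoms
cycle: A/1/SG -> A/1/CB -> A/1/CA -> A/1/C -> A/2/N -> ... -> B/1/CB -> B/1/SG
with flanking residues: 28; after 0.05 A jitter: 28
```

The two CPPC copies and their two disulfides close a 28-atom macrocycle —
14 atoms per chain (SG-CB-CA-C through two prolines to N-CA-CB-SG) — and
the size is purely topological: flanking residues and coordinate noise do
not change it.

```
$ python analysis/01_atom_census.py
           L/M chain  H/V chain  H+V glycans  Total
C               1020       2218          118   6594
N                270        582            8   1712
O                330        674           83   2091
S                  7         17            0     48
H               1574       3435          196  10214
Total           3201       6926          405  20659
Routes agree cell-for-cell: True; audit discrepancies: 0
```

The same table is produced twice — once by sequence-level arithmetic, once
by counting the atoms of a fully built 20,659-atom model — and the two
routes must agree exactly, per chain and per element.

`analysis/02_assemble_five_parts.py` shows the five-part graft recovering a
known assembly to ~1e-12 Å after random rigid displacement of every part;
`analysis/04_minimize_spliced_hinge.py` relaxes a freshly spliced hinge
until every peptide bond is 1.329 ± 0.001 Å and both disulfides 2.05 Å;
`analysis/05_canonical_frame.py` recovers a dyad axis and reframes a model
with the origin residual at machine precision.

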