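# Methods

## Scope and data model

The package rebuilds a whole IgG1 antibody from fragment coordinates and
audits the result. The in-memory model is deliberately plain: chains of
residues of atoms (elements restricted to C/H/N/O/S, the full alphabet of a
glycoprotein), plus explicit covalent links for everything the
residue-chain topology does not imply — disulfides (SG–SG), glycosidic
(C1–O) and N-glycosidic (C1–ND2) bonds. Peptide bonds are implied between
consecutive residues of a chain and never stored. File I/O goes through
gemmi (PDB and mmCIF in, PDB v3.3 out: ATOM/HETATM/SSBOND/LINK/TER);
alternate locations collapse to the highest-occupancy conformer with ties
broken toward altloc A, matching the single-conformer model deposited.

## Residue templates

All ideal geometry — atom sets, coordinates, covalent bonds — comes from
the Chemical Component Dictionary bundled with biotite, specialized to
in-polymer forms: free-monomer leaving groups (OXT/HXT, the second amine
hydrogen) are dropped except at termini; pyroglutamate (PCA) is the
N-terminal cyclized Gln; sugars lose the anomeric O1/HO1 when linked and
the hydroxyl hydrogen at each outgoing linkage. Because the backbone
placement constants are measured from the same templates, a freshly built
residue superposes onto its template exactly, and ideal fixtures sit at the
surrogate potential's minimum to machine precision — a deliberate
consistency that makes "zero strain" a meaningful reference point.

## Composition bookkeeping

Chain composition = Σ free monomers − (n−1)·H₂O, minus NH₃ for a
pyroglutamate N-terminus, minus one H per disulfide half-cystine, minus one
H per N-glycosylated Asn. Glycan composition = Σ free sugars − (edges)·H₂O,
minus OH at the root when protein-linked: the N-glycosidic bond is split so
that per-chain and glycan columns of a census table are each well defined.

Protonation is a two-valued switch. The published per-chain totals fix it
unambiguously: with ionized side chains (Lys/Arg +1 H, Asp/Glu −1 H,
His neutral) and neutral termini, the packaged sequences reproduce every
cell of the reference census (light chain 3201 atoms, heavy 6926, glycans
405, total 20659); with charged termini the heavy chain — whose
pyroglutamate blocks the N-terminal proton — comes out one hydrogen short.
The ``neutral`` convention (every group neutral) is kept as the alternate.
The same conventions drive hydrogen placement, so the sequence-level
arithmetic and the atom count of a built structure agree exactly; the
`audit_against_sequence` report is the difference of the two routes and is
empty for a consistent model.

The packaged heavy (450 aa) and light (213 aa) sequences are the public
reference-material sequences; the ten per-chain per-element counts above
over-determine them, and all ten match.

## Assembly protocol

The five-part graft (two Fabs, Fc, upper hinge with the CPPC disulfide
core, lower hinge) starts from the hinge donor as scaffold, since the hinge
conformation is inherited from it. Every other part is rigidly superposed
through the backbone N/CA/C of at least three shared junction residues
(gate: RMSD ≤ 2 Å, otherwise the parts are declared incompatible) and
contributes exactly the residues it owns; ownership ranges are
configuration, with crystal-quality coordinates kept wherever available.
Covalent links whose atoms both survive are carried and deduplicated.

Splicing closes the gap left by deleting donor surplus: the anchor
residue's backbone frame is recorded *before* deletion, the first retained
downstream residue is mapped N→N, CA→CA, C→C onto that frame, and the
whole downstream fragment moves rigidly; both heavy chains are spliced with
the same specification. Mutations keep N/CA/C/O and CB (when shared) and
hang the ideal template side chain off the preserved CB — the template's
own conformation is the single deterministic rotamer, with a small χ₁ scan
(0, ±120°, 180°, ±60°) used only if a rebuilt heavy atom comes within
2.0 Å of a non-bonded heavy atom. Terminus extension appends residues in
ideal extended geometry, re-orienting the former terminal carbonyl so the
new peptide plane is exact. Residual strain at all of these seams is the
minimizer's job, not the builders'.

Hydrogens are placed per residue from template frames (parent heavy atom
plus two bonded neighbours), so side chains keep hydrogens consistent with
their actual rotamer; the mid-chain amide H is the one cross-residue case
and is placed analytically, trans on the C(prev)–N–CA bisector. Which
hydrogens exist follows the composition conventions (half-cystines lose HG,
glycosylated Asn loses HD22, bridge oxygens lose their hydroxyl H).

## Surrogate potential and staged minimization

The potential is harmonic bonds + harmonic angles + purely repulsive
soft-sphere contacts with 1-2/1-3 exclusions. Ideal bond lengths and
intra-residue angles are measured from the templates; inter-residue angles
use standard peptide values (CA-C-N 116.2°, C-N-CA 121.7°, the carbonyl
O-C-N closing the sp² triangle); contact diameters are 0.75 × the sum of
per-element radii (C 1.70, N 1.55, O 1.52, S 1.80, H 1.10 Å), chosen so
ideal conformations are contact-free. Force constants (300 Å⁻², 80 rad⁻²,
50 Å⁻²) set only the relative stiffness; energies are in arbitrary units
throughout. Torsions are deliberately absent: bonds, angles and repulsion
suffice to restore local geometry at seams, which is this potential's whole
job — it makes no claim to conformational energetics, and published
force-field energy values are out of scope.

Minimization runs a fixed 500 steepest-descent steps then 500
Polak–Ribière conjugate-gradient steps (β⁺ clamp, restart on loss of
descent), no early stopping, so trace lengths are deterministic. Step
lengths come from a directional-curvature estimate — exact on quadratics,
so CG retains its finite-termination property, verified against a direct
linear solve — guarded by backtracking that accepts only non-increasing
energy. The per-step record is (step, phase, energy, max |gradient
component|). On the analysis fixtures this relaxes spliced peptide bonds to
1.329 ± 0.001 Å and disulfides to 2.05 ± 0.01 Å; the trace is reproduced
qualitatively (decreasing envelope), never numerically.

## Canonical frame and metrics

The dyad is the rotation superposing the Fc CA set of one heavy chain onto
the other: its angle must be within 10° of 180°, its axis is the fixed
line of the transform (least-squares solution of (R−I)p = −t), and the
axis point is the projection of the combined centroid. The canonical frame
sends the dyad to z — sign chosen so the Fc centre of mass lies below the
xy plane — and the midpoint of the two Pro241 CA atoms to the origin. The
text fixes only origin and z; the in-plane orientation is made
deterministic by putting the centroid of the first heavy chain's Fab lobe
at positive x. Radius of gyration is reported in nm, mass-weighted with
hydrogens included as the headline (uniform weighting is always computed
alongside, since the deposited value's convention is unstated and the two
differ by less than the quoted tolerance); masses are standard atomic
weights to 4 decimals. The hinge bend is the angle between best-fit CA
lines of the two window halves, measured like a bond angle (collinear →
180°).

## Ring analysis

The minimal covalent ring through the two hinge disulfides is a
two-vertex-disjoint-paths problem: two independent shortest paths can
illegally share atoms, so the search is a unit-capacity min-cost flow
(node splitting, sources at one disulfide's sulfurs, sinks at the other's),
which is exact; adjacent-edge degenerate cases fall back to a single
shortest path. Hydrogens are excluded (degree 1, never on a cycle).
Correctness is checked against brute-force enumeration of all simple cycles
on random graphs of up to 14 nodes. For the paired CPPC core the ring is 28
atoms — 14 per chain — independent of flanks and of coordinate noise.

## Synthetic fixtures and what they do (not) show

All tests run offline on generated inputs: ideal peptides (extended
φ=ψ=180° or helical −57°/−47°), a paired hinge whose second chain is
translated 2.05 Å along the inter-sulfur direction and flipped 180° about
the SG–SG line (both disulfides exactly at bond length), exact C2 dimers,
and a five-part plan cut from a known ground-truth assembly with seeded
random rigid displacements, so reassembly must invert them. The full-scale
synthetic model uses the real 450/213-residue sequences with complete
covalent topology (PCA, all disulfides, both glycans, hydrogens) but
idealized extended geometry. These fixtures validate bookkeeping, topology
and rigid-body machinery exactly; they are not antibody folds, so
conformation-dependent quantities (radius of gyration, lobe extents) are
only meaningful on real fragment inputs, which the `configs/` route accepts
when the crystal-structure files are supplied locally. The shipped residue
ranges in that configuration follow the model's sequential numbering and
must be reconciled with the local files' own numbering before use.

## Numerical choices and limitations

Degenerate inputs fail loudly: fewer than three or collinear superposition
points, non-dyad rotations (>10° from 180°), SG–SG beyond 8 Å (2.5–8 Å
forms the bond with a warning, leaving closure to the minimizer), missing
backbone atoms at a splice. Determinism is absolute: no unseeded
randomness anywhere, ties in altloc and rotamer selection broken by fixed
order, fixture generators bitwise-reproducible per seed (NumPy PRNG).
Known limitations: no multi-model files or crystallographic symmetry; no
torsional or electrostatic energetics; no loop or CDR remodeling; the
mutation rotamer set is minimal by design; PDB output is capped at 99,999
atoms (mmCIF is suggested beyond).
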