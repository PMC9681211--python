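# Crystal-structure input route for the whole-antibody build.
#
# Requires the three fragment coordinate files locally (they are not
# distributed with the package); download them into data/pdb/ first:
#   data/pdb/fab.pdb    - the Fab fragment crystal structure (used twice)
#   data/pdb/fc.pdb     - the Fc fragment crystal structure (carries glycans)
#   data/pdb/hinge.pdb  - a whole-antibody structure donating the hinge,
#                         including the intact paired-CPPC disulfide core
#
# Residue ranges below use the model's sequential numbering (heavy 1-450,
# light 1-213; hinge span 220-246).  Fragment depositions use their own
# numbering and chain names: renumber/rename the local files to this scheme
# (or adjust chain_map/ranges here) before running.  The hinge edit removes
# the donor's two surplus residues after the CPPC core and splices the
# following proline onto the deleted lysine's backbone frame, on both heavy
# chains simultaneously.

inputs:
  fab: data/pdb/fab.pdb
  fc: data/pdb/fc.pdb
  hinge_donor: data/pdb/hinge.pdb

protonation: charged

hinge:
  edit_scripts: []        # hinge mutations to the target sequence, per chain
  splice:
    chains: [H, V]
    anchor: 233           # the deleted lysine position (donor scheme)
    downstream_first: 235 # the first retained proline of PAPN...

parts:
  upper_hinge:
    chain_map: {H: H, V: V}
    owned: {H: [[220, 232]], V: [[220, 232]]}
  lower_hinge:
    chain_map: {H: H, V: V}
    owned: {H: [[233, 246]], V: [[233, 246]]}
  fab1:
    chain_map: {H: H, L: L}
    owned: {H: [[1, 219]], L: [[1, 213]]}
  fab2:
    chain_map: {H: V, L: M}
    owned: {V: [[1, 219]], M: [[1, 213]]}
  fc:
    chain_map: {A: H, B: V}
    owned: {H: [[247, 450], [601, 609]], V: [[247, 450], [601, 608]]}

junctions:
  - a: upper_hinge
    b: fab1
    shared: [[H, 220], [H, 221], [H, 222]]
  - a: upper_hinge
    b: fab2
    shared: [[V, 220], [V, 221], [V, 222]]
  - a: upper_hinge
    b: lower_hinge
    shared: [[H, 230], [H, 231], [H, 232], [V, 230], [V, 231], [V, 232]]
  - a: lower_hinge
    b: fc
    shared: [[H, 247], [H, 248], [H, 249], [V, 247], [V, 248], [V, 249]]

extensions:
  - chain: H
    residues: PGK
    end: C
  - chain: V
    residues: PGK
    end: C
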