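"""NISTmAb RM 8671 reference data.

The packaged FASTA holds the public reference-material chain sequences
(heavy 450 aa, light 213 aa).  Landmarks used throughout the pipeline, all in
the model's plain sequential numbering: the N-glycosylation site Asn300, the
hinge span 220-246 with its CPPC disulfide core at 229-232, the GGP bend at
239-241, and Pro241 whose paired CA atoms define the reference-frame origin.

The heavy chain carries pyroglutamate at its N-terminus and either the
9-sugar G1F glycan (chain H) or the 8-sugar G0F glycan (chain V); every
cysteine of an IgG1 is engaged in a disulfide.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .composition import (
    ChainSpec,
    census_table,
    chain_composition,
    g0f,
    g1f,
    glycan_composition,
)
from .errors import ChemistryError

GLYCOSYLATION_SITE = 300
HINGE_SPAN = (220, 246)
CPPC_SPAN = (229, 232)
BEND_SPAN = (239, 241)
FRAME_PROLINE = 241
GLYCAN_FIRST_SEQ_NUM = 601  # glycan residues numbered from 601 on each heavy chain


def load_sequences() -> dict[str, str]:
    """Return {'heavy': ..., 'light': ...} from the packaged FASTA."""
    from .structure_io import read_fasta

    path = resources.files("mabstitch.data") / "nistmab.fasta"
    entries = dict(read_fasta(str(path)))
    heavy = next(v for k, v in entries.items() if k.startswith("heavy"))
    light = next(v for k, v in entries.items() if k.startswith("light"))
    return {"heavy": heavy, "light": light}


def igg1_disulfide_pairs(heavy: str, light: str) -> dict[str, list]:
    """Standard IgG1 disulfide topology from the cysteine pattern.

    Light chains carry 5 cysteines: two sequential intra-domain pairs plus the
    C-terminal Cys bonded to the heavy chain.  Heavy chains carry 11: VH and
    CH1 intra pairs, the light-chain partner, the two hinge-core (CPPC)
    cysteines forming the inter-heavy bridges, then CH2 and CH3 intra pairs.
    Returns 1-based residue numbers.
    """
    lc = [i + 1 for i, a in enumerate(light) if a == "C"]
    hc = [i + 1 for i, a in enumerate(heavy) if a == "C"]
    if len(lc) != 5 or len(hc) != 11:
        raise ChemistryError(
            f"not an IgG1 cysteine pattern (light {len(lc)}, heavy {len(hc)})"
        )
    core = heavy.find("CPPC") + 1
    if core == 0:
        raise ChemistryError("heavy chain lacks the CPPC hinge core")
    hinge = [core, core + 3]
    inter_l = [c for c in hc if c not in hinge][4]  # 5th non-hinge Cys
    intra_h = [c for c in hc if c not in hinge and c != inter_l]
    return {
        "light_intra": [(lc[0], lc[1]), (lc[2], lc[3])],
        "light_heavy": (lc[4], inter_l),
        "heavy_intra": [
            (intra_h[0], intra_h[1]),
            (intra_h[2], intra_h[3]),
            (intra_h[4], intra_h[5]),
            (intra_h[6], intra_h[7]),
        ],
        "heavy_heavy": [(hinge[0], hinge[0]), (hinge[1], hinge[1])],
    }


def chain_specs(protonation: str = "charged") -> dict[str, ChainSpec]:
    """Sequence-level ChainSpec per model chain (H, L, V, M)."""
    seqs = load_sequences()
    heavy, light = seqs["heavy"], seqs["light"]
    # every Cys of an IgG1 is disulfide-engaged
    n_h, n_l = heavy.count("C"), light.count("C")
    return {
        "H": ChainSpec(heavy, n_term="pyroglutamate", n_disulfide_half_cystines=n_h, glycan=g1f()),
        "V": ChainSpec(heavy, n_term="pyroglutamate", n_disulfide_half_cystines=n_h, glycan=g0f()),
        "L": ChainSpec(light, n_disulfide_half_cystines=n_l),
        "M": ChainSpec(light, n_disulfide_half_cystines=n_l),
    }


def predicted_census(protonation: str = "charged") -> pd.DataFrame:
    """Whole-antibody census table predicted from the sequences alone."""
    seqs = load_sequences()
    light = chain_composition(
        seqs["light"],
        n_disulfide_half_cystines=seqs["light"].count("C"),
        protonation=protonation,
    )
    heavy = chain_composition(
        seqs["heavy"],
        n_term="pyroglutamate",
        n_disulfide_half_cystines=seqs["heavy"].count("C"),
        n_glycosylation_sites=1,
        protonation=protonation,
    )
    glycans = glycan_composition(g1f(), linked_to_protein=True) + glycan_composition(
        g0f(), linked_to_protein=True
    )
    return census_table(light, heavy, glycans)
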