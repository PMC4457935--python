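"""Synthetic reference coding sequence for tests and simulations.

No reference sequence or reads accompany the study this pipeline emulates, so
the package ships a SYNTHETIC 150-codon CDS.  It is not the E. coli recA
gene: only the residue identities at the window positions that matter for
variant naming (V79, A81, E86, C90, I93, H97, D100, I102, A104, D110, D112,
N113, E127, C129, A131, L132, G136, A137) are placed as in the protein the
screen targeted, and their codons are chosen so the documented amino-acid
changes (V79L, E86G, C90G, I93L, H97Y, D100A, I102L, N113I, ...) are each
reachable by a single nucleotide substitution.  Everything else is arbitrary
but deterministic.
"""

from __future__ import annotations

from Bio.Seq import Seq

from .library_model import BASES, TargetRegion

# Residues 79..137 of the synthetic protein (59 aa).  Named positions match
# the screen's target; fillers are arbitrary.
WINDOW_AA = "VSAGKTLEFDICYGIPMGHRLDPIYARKLGVDIDNLLCSQPDTGEQALEICDALARSGA"

# One codon per amino acid; picked so the variants of interest are single-nt
# reachable (e.g. GTT->CTT gives V->L, GAA->GGA gives E->G, TGT->GGT C->G,
# ATT->CTT I->L, CAT->TAT H->Y, GAT->GCT D->A, AAT->ATT N->I, GGT->CGT G->R).
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

_FLANK_CYCLE = "AEGKLRSTVDNQIFPHM"

WINDOW_CODON_START = 79
WINDOW_CODON_END = 137
N_CODONS = 150


def synthetic_cds() -> str:
    """Deterministic 450-nt synthetic CDS with the 59-aa window at 79-137."""
    aa = ["M"]
    i = 0
    while len(aa) < WINDOW_CODON_START - 1:
        aa.append(_FLANK_CYCLE[i % len(_FLANK_CYCLE)])
        i += 1
    aa.extend(WINDOW_AA)
    i = 0
    while len(aa) < N_CODONS:
        aa.append(_FLANK_CYCLE[(i + 5) % len(_FLANK_CYCLE)])
        i += 1
    return "".join(_CODON[a] for a in aa)


def default_region() -> TargetRegion:
    """The synthetic CDS with the standard 59-codon mutagenesis window."""
    return TargetRegion(
        cds_sequence=synthetic_cds(),
        codon_start=WINDOW_CODON_START,
        codon_end=WINDOW_CODON_END,
    )


def substitution_for_aa_change(
    region: TargetRegion, label: str
) -> tuple[int, str, str]:
    """A single-nucleotide substitution realising an amino-acid change label.

    ``label`` is one-letter style, e.g. ``"V79L"``.  The codon's three
    positions and the alternative bases are searched in a fixed order, so the
    choice is deterministic.  Raises if the reference residue does not match
    or no single-nucleotide route exists.
    """
    ref_aa, pos_str, new_aa = label[0], label[1:-1], label[-1]
    residue = int(pos_str)
    if not region.codon_start <= residue <= region.codon_end:
        raise ValueError(f"residue {residue} outside window "
                         f"{region.codon_start}-{region.codon_end}")
    codon_nt_start = 3 * (residue - 1) + 1
    codon = region.cds_sequence[codon_nt_start - 1 : codon_nt_start + 2]
    if str(Seq(codon).translate()) != ref_aa:
        raise ValueError(
            f"reference codon {codon} at residue {residue} encodes "
            f"{Seq(codon).translate()}, not {ref_aa}"
        )
    for offset in range(3):
        for alt in BASES:
            if alt == codon[offset]:
                continue
            mutated = codon[:offset] + alt + codon[offset + 1 :]
            if str(Seq(mutated).translate()) == new_aa:
                return (codon_nt_start + offset, codon[offset], alt)
    raise ValueError(f"no single-nucleotide route for {label} from codon {codon}")
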