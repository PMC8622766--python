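"""Controlled vocabulary and reference constants for insect mitogenomes.

A typical insect mitochondrial genome is a circular molecule of 14-20 kb
carrying 37 genes -- 13 protein-coding genes (PCGs), 22 transfer RNAs and
two ribosomal RNAs -- plus one long A+T-rich non-coding stretch, the
control region (CR).  Genes are distributed over the two strands, called
the majority (J) and minority (N) strand: in the plesiomorphic
(ancestral) arrangement nine PCGs and 14 tRNAs sit on J, the remaining
four PCGs, eight tRNAs and both rRNAs on N.

Everything downstream of the readers keys on the canonical labels defined
here.  The two duplicated-isoacceptor tRNAs are disambiguated the way the
mitogenomics literature does: trnL1 reads CUN codons (anticodon UAG),
trnL2 reads UUR (UAA); trnS1 reads AGN (GCU/UCU), trnS2 reads UCN (UGA).
"""

from __future__ import annotations

J = "J"  # majority strand (forward strand of the deposited sequence)
N = "N"  # minority strand

PCGS: tuple[str, ...] = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COX1", "COX2", "COX3", "ATP6", "ATP8", "CYTB",
)

TRNAS: tuple[str, ...] = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

RRNAS: tuple[str, ...] = ("rrnS", "rrnL")

CR = "CR"
NCR = "NCR"

CANONICAL_GENES: tuple[str, ...] = PCGS + TRNAS + RRNAS

#: one-letter amino acid carried by each tRNA label (isoacceptor number dropped)
TRNA_AMINO = {t: t[3] for t in TRNAS}

# categories --------------------------------------------------------------

PCG_CAT, TRNA_CAT, RRNA_CAT, CR_CAT, NCR_CAT = "PCG", "tRNA", "rRNA", "CR", "NCR"


def category_of(label: str) -> str:
    """Feature category for a canonical label; 'unknown' otherwise."""
    if label in PCGS:
        return PCG_CAT
    if label in TRNAS:
        return TRNA_CAT
    if label in RRNAS:
        return RRNA_CAT
    if label == CR:
        return CR_CAT
    if label == NCR or label.startswith("NCR"):
        return NCR_CAT
    return "unknown"


def is_ncr_label(label: str) -> bool:
    """True for NCR placeholders (NCR, NCR_2, ...) -- products of
    rearrangement, not markers, so distance computations skip them."""
    return label == NCR or label.startswith("NCR_") or label.startswith("NCR")


# ancestral insect (pancrustacean) gene order -----------------------------
#
# Signed circular order; +1 = J strand, -1 = N strand.  The CR closes the
# circle between rrnS and trnI.

ANCESTRAL_ORDER: tuple[tuple[str, int], ...] = (
    ("trnI", +1), ("trnQ", -1), ("trnM", +1), ("ND2", +1),
    ("trnW", +1), ("trnC", -1), ("trnY", -1),
    ("COX1", +1), ("trnL2", +1), ("COX2", +1), ("trnK", +1), ("trnD", +1),
    ("ATP8", +1), ("ATP6", +1), ("COX3", +1), ("trnG", +1), ("ND3", +1),
    ("trnA", +1), ("trnR", +1), ("trnN", +1), ("trnS1", +1), ("trnE", +1),
    ("trnF", -1), ("ND5", -1), ("trnH", -1), ("ND4", -1), ("ND4L", -1),
    ("trnT", +1), ("trnP", -1), ("ND6", +1), ("CYTB", +1), ("trnS2", +1),
    ("ND1", -1), ("trnL1", -1), ("rrnL", -1), ("trnV", -1), ("rrnS", -1),
    ("CR", +1),
)

#: the trnQ-NCR-trnI-trnM arrangement: trnI and trnQ swap positions
#: (strands unchanged) and a non-coding remnant sits between them.
REARRANGED_IQ_ORDER: tuple[tuple[str, int], ...] = (
    ("trnQ", -1), ("NCR", +1), ("trnI", +1), ("trnM", +1),
) + ANCESTRAL_ORDER[3:]

ANCESTRAL_STRAND: dict[str, str] = {
    label: (J if sign > 0 else N) for label, sign in ANCESTRAL_ORDER
}

COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                           "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(COMPLEMENT)[::-1]
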