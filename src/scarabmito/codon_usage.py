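"""Codon counting, RSCU, and start/stop codon identification.

All translation uses the invertebrate mitochondrial genetic code
(NCBI translation table 5), under which ATA is Met, TGA is Trp and
AGA/AGG are Ser.  Synonymous families follow mitogenomics practice in
splitting the two-isoacceptor amino acids: Leu1 = CUN, Leu2 = UUR,
Ser1 = AGN, Ser2 = UCN.  RSCU(c) = count(c) * k / sum of family counts,
with k the family size, so the mean RSCU over a used family is exactly 1.

Start-codon identification implements the minimize-intergenic-space
rule used when annotating mitochondrial PCGs: among candidate start
trinucleotides in frame with the annotated open reading frame and not
overlapping the upstream gene, the one closest to the upstream gene
wins, with canonical ATN preferred over atypical AAN (AAC/AAT), and
those over the rarer alternatives (GTC, GTG, TTG, CAA, CGA, AAA, CTA),
when offsets tie.  An atypical codon strictly closer than the nearest
canonical ATN therefore wins -- the situation that makes AAC/AAT the
accepted COX1 start in many polyphagan beetles.

Stop codons may be complete (TAA/TAG) or incomplete (TA/T), the latter
completed to TAA by post-transcriptional polyadenylation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Data import CodonTable

from .genes import J, N, revcomp
from .mito_io import GeneFeature, Mitogenome, extract_gene_sequence

__all__ = [
    "CodonUsageTable", "StartStopCall", "count_codons", "rscu",
    "amino_acid_composition", "identify_start_codon", "identify_stop_codon",
    "FAMILIES", "STOP_CODONS", "CANONICAL_STARTS", "AAN_STARTS", "OTHER_STARTS",
]

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
STOP_CODONS: frozenset[str] = frozenset(_TABLE5.stop_codons)  # TAA, TAG

_AA3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}


def family_of(codon: str) -> str:
    """Synonymous-family label of a sense codon (Leu/Ser split)."""
    aa = _TABLE5.forward_table[codon]
    if aa == "L":
        return "Leu1" if codon.startswith("C") else "Leu2"
    if aa == "S":
        return "Ser1" if codon.startswith("A") else "Ser2"
    return _AA3[aa]


def _build_families() -> dict[str, tuple[str, ...]]:
    fams: dict[str, list[str]] = {}
    for codon in sorted(_TABLE5.forward_table):
        fams.setdefault(family_of(codon), []).append(codon)
    return {k: tuple(v) for k, v in fams.items()}


FAMILIES: dict[str, tuple[str, ...]] = _build_families()
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE5.forward_table))


@dataclass
class CodonUsageTable:
    """Sense-codon counts with optional RSCU values.

    ``total_codons`` excludes terminal stop codons (complete or
    incomplete) and codons skipped for ambiguity.
    """

    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in SENSE_CODONS})
    ambiguous_skipped: int = 0
    internal_stops: int = 0
    rscu: dict[str, float] = field(default_factory=dict)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())


def count_codons(cds_sequences: Iterable[str]) -> CodonUsageTable:
    """Tally codons over CDS sequences given in reading orientation.

    Each sequence is read in consecutive triplets from its first base;
    a trailing 1-2 nt remainder (an incomplete stop) is dropped, and a
    terminal complete stop codon is excluded from the tally.  Codons
    containing ambiguity codes are skipped and counted separately.
    In-frame stop codons occurring before the end are recorded in
    ``internal_stops`` (they indicate a mis-annotated frame).
    """
    t = CodonUsageTable()
    for seq in cds_sequences:
        seq = seq.upper()
        n_full = len(seq) // 3
        codons = [seq[3 * i: 3 * i + 3] for i in range(n_full)]
        if codons and codons[-1] in STOP_CODONS:
            codons.pop()
        for c in codons:
            if c in STOP_CODONS:
                t.internal_stops += 1
            elif c in t.counts:
                t.counts[c] += 1
            else:
                t.ambiguous_skipped += 1
    return t


def rscu(t: CodonUsageTable) -> CodonUsageTable:
    """Fill per-codon RSCU values in place (and return the table).

    Unused codons of an unused family get RSCU 0.
    """
    for fam, codons in FAMILIES.items():
        total = sum(t.counts[c] for c in codons)
        k = len(codons)
        for c in codons:
            t.rscu[c] = (t.counts[c] * k / total) if total else 0.0
    return t


def amino_acid_composition(t: CodonUsageTable) -> dict[str, int]:
    """Codon counts summed per amino acid, Leu1/Leu2 and Ser1/Ser2 split."""
    return {fam: sum(t.counts[c] for c in codons)
            for fam, codons in FAMILIES.items()}


# ---------------------------------------------------------------------------
# start / stop identification

CANONICAL_STARTS = frozenset({"ATA", "ATT", "ATC", "ATG"})
AAN_STARTS = frozenset({"AAC", "AAT"})
OTHER_STARTS = frozenset({"GTC", "GTG", "TTG", "CAA", "CGA", "AAA", "CTA"})

_START_CLASS = {"canonical-ATN": 0, "atypical-AAN": 1, "atypical-other": 2}


def start_class(codon: str) -> str | None:
    if codon in CANONICAL_STARTS:
        return "canonical-ATN"
    if codon in AAN_STARTS:
        return "atypical-AAN"
    if codon in OTHER_STARTS:
        return "atypical-other"
    return None


def start_candidate_rank(codon: str, offset: int) -> tuple[int, int]:
    """Sort key for candidate starts: nearest offset first, then class
    priority canonical > AAN > other on offset ties."""
    cls = start_class(codon)
    if cls is None:
        raise ValueError(f"{codon} is not a supported start codon")
    return (offset, _START_CLASS[cls])


@dataclass(frozen=True)
class StartStopCall:
    gene: str
    start_codon: str | None = None
    start_class: str | None = None
    start_offset: int | None = None  # bp from end of upstream gene
    stop_codon: str | None = None
    stop_class: str | None = None  # complete / incomplete
    flags: tuple[str, ...] = ()

    @property
    def no_call(self) -> bool:
        return "no-call" in self.flags


def _circ(seq: str, pos: int, n: int) -> str:
    """n bases starting at pos on the circular sequence."""
    L = len(seq)
    pos %= L
    if pos + n <= L:
        return seq[pos: pos + n]
    return seq[pos:] + seq[: (pos + n) % L]


def identify_start_codon(
    g: Mitogenome,
    pcg: GeneFeature,
    upstream: GeneFeature,
    window: int = 60,
) -> StartStopCall:
    """Call the start codon of ``pcg`` relative to its reading-upstream
    neighbour.

    Candidates are trinucleotides at offsets 0..window downstream of the
    upstream gene's 3' boundary, in frame with the annotated reading
    frame of ``pcg`` and not overlapping the upstream gene.  Ranking:
    minimal offset, then canonical ATN > AAN > other on ties.
    """
    L = len(g)
    seq = g.sequence
    if pcg.strand == J:
        boundary = upstream.end % L
        annotated_offset = (pcg.start - boundary) % L

        def codon_at(off: int) -> str:
            return _circ(seq, boundary + off, 3)
    else:
        boundary = upstream.start % L
        annotated_offset = (boundary - pcg.end) % L

        def codon_at(off: int) -> str:
            return revcomp(_circ(seq, boundary - off - 3, 3))

    best: tuple[tuple[int, int], str] | None = None
    for off in range(0, window + 1):
        if (off - annotated_offset) % 3:
            continue
        codon = codon_at(off)
        cls = start_class(codon)
        if cls is None:
            continue
        key = start_candidate_rank(codon, off)
        if best is None or key < best[0]:
            best = (key, codon)
    if best is None:
        return StartStopCall(gene=pcg.label, flags=("no-call",))
    (offset, _), codon = best
    return StartStopCall(gene=pcg.label, start_codon=codon,
                         start_class=start_class(codon), start_offset=offset)


def identify_stop_codon(
    g: Mitogenome,
    pcg: GeneFeature,
    downstream: GeneFeature | None = None,
) -> StartStopCall:
    """Call the stop codon of ``pcg`` from its annotated span.

    A terminal in-frame TAA/TAG is a complete stop; a 1-2 nt in-frame
    remainder of T or TA abutting the downstream gene is an incomplete
    stop (completed by polyadenylation of the mature mRNA).  An in-frame
    stop strictly before the annotated end raises a premature-stop flag.
    """
    seq = extract_gene_sequence(g, pcg)
    n_full = len(seq) // 3
    remainder = seq[3 * n_full:]
    flags: list[str] = []
    for i in range(n_full - 1):
        if seq[3 * i: 3 * i + 3] in STOP_CODONS:
            flags.append("premature-stop")
            break
    last = seq[3 * (n_full - 1): 3 * n_full] if n_full else ""
    if not remainder and last in STOP_CODONS:
        stop, cls = last, "complete"
    elif remainder == "T":
        stop, cls = "T", "incomplete"
    elif remainder == "TA":
        stop, cls = "TA", "incomplete"
        flags.append("incomplete-TA")
    else:
        return StartStopCall(gene=pcg.label, flags=tuple(flags) + ("no-call",))
    return StartStopCall(gene=pcg.label, stop_codon=stop, stop_class=cls,
                         flags=tuple(flags))
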