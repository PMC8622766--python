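"""Overlaps, intergenic spacers, motifs, homopolymers, tandem repeats and
control-region location on the circular genome.

Adjacent-feature spacers are signed: negative lengths are overlaps,
zero means abutting genes, positive lengths are intergenic spacers
(IGS).  Because the molecule is circular, the pair spanning the origin
is included, and feature lengths plus signed spacer lengths always sum
to the genome length.

The tandem-repeat finder is exact-match only (no alignment tolerance):
maximal arrays of a repeated unit, reported once under their smallest
period, with possibly fractional copy number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .composition import base_counts
from .genes import CR, revcomp
from .mito_io import GeneFeature, Mitogenome

__all__ = [
    "SpacerRecord", "RepeatRecord", "ControlRegionSummary",
    "adjacent_spacers", "find_motif", "homopolymer_runs",
    "exact_tandem_repeats", "locate_control_region",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class SpacerRecord:
    """Signed gap between circularly adjacent features."""

    upstream: str
    downstream: str
    length: int  # negative = overlap, 0 = abutting, positive = IGS
    sequence: str = ""
    motif_hits: tuple[tuple[str, int], ...] = ()


@dataclass(frozen=True)
class RepeatRecord:
    unit_length: int
    copy_number: float
    start: int
    unit_sequence: str

    def validates_on(self, seq: str) -> bool:
        """Re-check by direct substring comparison."""
        span = int(self.copy_number * self.unit_length)
        region = seq[self.start: self.start + span]
        tiled = (self.unit_sequence * math.ceil(self.copy_number))[: span]
        return region == tiled and self.copy_number >= 2


def _forward_span(g: Mitogenome, start: int, end: int) -> str:
    L = len(g)
    if end <= L:
        return g.sequence[start:end]
    return g.sequence[start:] + g.sequence[: end - L]


def adjacent_spacers(
    g: Mitogenome,
    motifs: tuple[str, ...] = (),
    both_strands: bool = False,
) -> list[SpacerRecord]:
    """One record per circularly adjacent feature pair, including the
    pair spanning the origin.

    Features fully nested inside another are excluded from the chain
    (with a warning) so that the circular length conservation
    ``sum(features) + sum(spacers) == genome length`` holds.  When
    ``motifs`` are given, each positive spacer is scanned on its forward
    strand (optionally both strands).
    """
    feats = sorted(g.features, key=lambda f: (f.start, f.end))
    if len(feats) < 2:
        raise ValueError("need at least two features")
    chain: list[GeneFeature] = []
    nested = []
    for f in feats:
        if any(o is not f and o.start <= f.start and f.end <= o.end for o in feats):
            nested.append(f.label)
            continue
        chain.append(f)
    if nested:
        warnings.warn(f"{g.accession}: nested features excluded from spacer chain: {nested}")
    L = len(g)
    records = []
    for k, f in enumerate(chain):
        nxt = chain[(k + 1) % len(chain)]
        if k + 1 < len(chain):
            gap = nxt.start - f.end
        else:
            gap = nxt.start + L - f.end  # across the origin
        seq = _forward_span(g, f.end % L, f.end % L + gap) if gap > 0 else ""
        hits: list[tuple[str, int]] = []
        for m in motifs:
            hits.extend((m, off) for off in find_motif(seq, m))
            if both_strands:
                hits.extend((m, off) for off in find_motif(revcomp(seq), m))
        records.append(SpacerRecord(upstream=f.label, downstream=nxt.label,
                                    length=gap, sequence=seq,
                                    motif_hits=tuple(hits)))
    return records


def find_motif(seq: str, motif: str) -> list[int]:
    """All 0-based offsets of an IUPAC motif; overlapping hits allowed."""
    motif = motif.upper()
    sets = []
    for ch in motif:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r}")
        sets.append(IUPAC[ch])
    seq = seq.upper()
    m = len(motif)
    return [i for i in range(len(seq) - m + 1)
            if all(seq[i + k] in sets[k] for k in range(m))]


def homopolymer_runs(seq: str, min_len: int) -> list[tuple[str, int, int]]:
    """Maximal single-base runs of length >= min_len as (base, start, length)."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((seq[i], i, j - i))
        i = j
    return runs


def exact_tandem_repeats(
    seq: str,
    unit_range: tuple[int, int] = (2, 200),
    min_copies: float = 2.0,
) -> list[RepeatRecord]:
    """Maximal exact tandem arrays, O(n * max_unit) brute force.

    Each array is reported once, under its smallest period; arrays whose
    smallest period falls below ``unit_range[0]`` are therefore not
    reported at a larger multiple of that period.
    """
    n = len(seq)
    lo, hi = unit_range
    lo = max(lo, 1)
    hi = min(hi, n // 2)
    out: list[RepeatRecord] = []
    for u in range(lo, hi + 1):
        p = 0
        while p + 2 * u <= n:
            if seq[p: p + u] != seq[p + u: p + 2 * u]:
                p += 1
                continue
            # extend base by base past the second copy
            ext = 2 * u
            while p + ext < n and seq[p + ext] == seq[p + ext - u]:
                ext += 1
            unit = seq[p: p + u]
            copies = ext / u
            left_maximal = p == 0 or seq[p - 1] != seq[p + u - 1]
            if copies >= min_copies and left_maximal and _smallest_period(unit) == u:
                out.append(RepeatRecord(unit_length=u, copy_number=copies,
                                        start=p, unit_sequence=unit))
            p += ext - u + 1  # restart past this array
    return sorted(out, key=lambda r: (r.start, r.unit_length))


def _smallest_period(unit: str) -> int:
    u = len(unit)
    for p in range(1, u):
        if u % p == 0 and unit == unit[:p] * (u // p):
            return p
    return u


@dataclass(frozen=True)
class ControlRegionSummary:
    feature: GeneFeature | None
    length: int
    at_fraction: float
    bounded_by: tuple[str, str]
    zero_length: bool = False


def locate_control_region(g: Mitogenome) -> ControlRegionSummary:
    """The control region as the span from the end of rrnS to the start
    of the next annotated gene, circularly.

    In the ancestral arrangement that downstream gene is trnI; in the
    rearranged trnQ-NCR-trnI-trnM arrangement it is trnQ.  Annotated
    CR/NCR features are not counted as bounding genes.  A zero-length
    span is flagged rather than raising.
    """
    try:
        rrns = g.feature("rrnS")
    except KeyError:
        raise ValueError("rrnS not annotated; cannot locate control region")
    L = len(g)
    genes = [f for f in g.features
             if f.category in ("PCG", "tRNA", "rRNA") and f.label != "rrnS"]
    if not genes:
        raise ValueError("no bounding genes annotated")
    nxt = min(genes, key=lambda f: (f.start - rrns.end) % L)
    start = rrns.end % L
    length = (nxt.start - rrns.end) % L
    if length == 0:
        return ControlRegionSummary(feature=None, length=0, at_fraction=math.nan,
                                    bounded_by=("rrnS", nxt.label), zero_length=True)
    cr_seq = _forward_span(g, start, start + length)
    feat = GeneFeature(label=CR, category="CR", strand="J",
                       start=start, end=start + length)
    return ControlRegionSummary(feature=feat, length=length,
                                at_fraction=base_counts(cr_seq).at_fraction,
                                bounded_by=("rrnS", nxt.label))
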