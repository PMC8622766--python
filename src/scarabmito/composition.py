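"""Base composition and strand-asymmetry (skew) statistics.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), computed on the
forward (J) strand unless a region is explicitly read in gene
orientation.  Skews measure the strand bias left by asymmetric
replication/transcription of the mitochondrial molecule; AT fraction is
the classic A+T richness of insect mtDNA.  Ambiguity codes (N etc.) are
counted separately and excluded from every denominator, since the skew
formulas are defined on A, C, G, T only.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable

from .genes import revcomp
from .mito_io import GeneFeature, Mitogenome, extract_gene_sequence

__all__ = ["CompositionStats", "base_counts", "at_skew", "gc_skew",
           "region_composition", "SELECTORS"]


@dataclass(frozen=True)
class CompositionStats:
    count_a: int = 0
    count_c: int = 0
    count_g: int = 0
    count_t: int = 0
    ambiguous: int = 0

    @property
    def total(self) -> int:
        """ACGT bases only (ambiguity codes excluded)."""
        return self.count_a + self.count_c + self.count_g + self.count_t

    @property
    def at_fraction(self) -> float:
        return (self.count_a + self.count_t) / self.total if self.total else math.nan

    @property
    def skew_at(self) -> float:
        d = self.count_a + self.count_t
        return (self.count_a - self.count_t) / d if d else math.nan

    @property
    def skew_gc(self) -> float:
        d = self.count_g + self.count_c
        return (self.count_g - self.count_c) / d if d else math.nan

    def __add__(self, other: "CompositionStats") -> "CompositionStats":
        return CompositionStats(
            self.count_a + other.count_a, self.count_c + other.count_c,
            self.count_g + other.count_g, self.count_t + other.count_t,
            self.ambiguous + other.ambiguous)


def base_counts(seq: str) -> CompositionStats:
    c = Counter(seq.upper())
    acgt = c["A"] + c["C"] + c["G"] + c["T"]
    return CompositionStats(c["A"], c["C"], c["G"], c["T"],
                            ambiguous=len(seq) - acgt)


def at_skew(seq: str) -> float:
    """(A - T)/(A + T); NaN when A + T = 0."""
    return base_counts(seq).skew_at


def gc_skew(seq: str) -> float:
    """(G - C)/(G + C); NaN when G + C = 0."""
    return base_counts(seq).skew_gc


# Named feature filters used throughout the reports.
SELECTORS: dict[str, Callable[[GeneFeature], bool]] = {
    "PCG": lambda f: f.category == "PCG",
    "PCG:J": lambda f: f.category == "PCG" and f.strand == "J",
    "PCG:N": lambda f: f.category == "PCG" and f.strand == "N",
    "tRNA": lambda f: f.category == "tRNA",
    "rRNA": lambda f: f.category == "rRNA",
    "CR": lambda f: f.category == "CR",
}


def _forward_span(g: Mitogenome, f: GeneFeature) -> str:
    L = len(g)
    if f.end <= L:
        return g.sequence[f.start:f.end]
    return g.sequence[f.start:] + g.sequence[: f.end - L]


def region_composition(
    g: Mitogenome,
    selector: str | Callable[[GeneFeature], bool] = "genome",
    orientation: str = "forward",
) -> CompositionStats:
    """Composition over the concatenation of selected features.

    ``selector`` may be ``"genome"`` (whole molecule), a key of
    :data:`SELECTORS`, a feature label, or a predicate on
    :class:`GeneFeature`.  By default every region is read in the
    genome's forward orientation regardless of coding strand, so that
    strand asymmetry between J- and N-encoded gene sets stays
    measurable; ``orientation="reading"`` instead reverse-complements
    N-strand features first.
    """
    if orientation not in ("forward", "reading"):
        raise ValueError("orientation must be 'forward' or 'reading'")
    if selector == "genome":
        return base_counts(g.sequence)
    if callable(selector):
        pred = selector
    elif selector in SELECTORS:
        pred = SELECTORS[selector]
    else:
        pred = lambda f, _lab=selector: f.label == _lab  # noqa: E731
    chosen = [f for f in g.features if pred(f)]
    if not chosen:
        raise ValueError(f"selector matched no features: {selector!r}")
    stats = CompositionStats()
    for f in chosen:
        seq = extract_gene_sequence(g, f) if orientation == "reading" else _forward_span(g, f)
        stats = stats + base_counts(seq)
    return stats
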