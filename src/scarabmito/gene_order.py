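"""Signed circular gene orders, rearrangement detection, and exhaustive
enumeration of single tandem-duplication-random-loss (TDRL) scenarios.

A gene order is a circular sequence of signed labels (+ = J strand).
Orders are compared as rotations but never reflections: the molecule has
a fixed reading strand, so reflecting would conflate an inversion with
identity.  Non-coding placeholders (NCR) are annotations produced by the
rearrangement and are excluded from distances and common-subsequence
computations.

Under the TDRL model a contiguous block is duplicated in tandem and one
copy of every duplicated gene is subsequently silenced and lost; the
unlost non-gene material of a decayed copy can persist as a non-coding
region (NCR).  A single TDRL can shuffle gene order inside the block but
can never change a gene's strand, and cannot produce a full reversal.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genes import ANCESTRAL_ORDER, REARRANGED_IQ_ORDER, is_ncr_label
from .mito_io import Mitogenome

__all__ = [
    "GeneOrder", "RearrangementReport", "TDRLScenario",
    "ANCESTRAL_GENE_ORDER", "REARRANGED_GENE_ORDER",
    "extract_gene_order", "normalize_rotation", "breakpoint_distance",
    "moved_genes", "classify_rearrangement", "enumerate_single_tdrl",
    "apply_tdrl", "classify_ncr",
]

SignedLabel = tuple[str, int]


def _parse_signed(token: str) -> SignedLabel:
    token = token.strip()
    if token.startswith("-"):
        return token[1:], -1
    return token.lstrip("+"), +1


def _fmt_signed(el: SignedLabel) -> str:
    label, sign = el
    return ("-" if sign < 0 else "") + label


@dataclass(frozen=True)
class GeneOrder:
    """Circular ordered sequence of signed gene labels.

    Two orders are equal iff one is a rotation of the other (signs
    included); reflections are *not* identified.
    """

    elements: tuple[SignedLabel, ...]

    @classmethod
    def from_strings(cls, tokens: Iterable[str]) -> "GeneOrder":
        """Build from tokens like ``trnI`` / ``-trnQ``."""
        return cls(tuple(_parse_signed(t) for t in tokens))

    @classmethod
    def from_text(cls, text: str) -> "GeneOrder":
        return cls.from_strings(text.split(","))

    def to_text(self) -> str:
        return ",".join(_fmt_signed(e) for e in self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.elements)

    def without_ncr(self) -> "GeneOrder":
        return GeneOrder(tuple(e for e in self.elements if not is_ncr_label(e[0])))

    def rotations(self):
        e = self.elements
        for i in range(len(e)):
            yield e[i:] + e[:i]

    def _canonical(self) -> tuple[SignedLabel, ...]:
        return min(self.rotations()) if self.elements else ()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self._canonical() == other._canonical()

    def __hash__(self) -> int:
        return hash(self._canonical())

    def index(self, label: str) -> int:
        return self.labels.index(label)


ANCESTRAL_GENE_ORDER = GeneOrder(ANCESTRAL_ORDER)
REARRANGED_GENE_ORDER = GeneOrder(REARRANGED_IQ_ORDER)


def extract_gene_order(g: Mitogenome) -> GeneOrder:
    """Gene order of an annotated genome, features sorted circularly by
    start.  NCR features are kept as labeled elements; flagged unknown
    features are skipped; duplicated canonical labels are an error and a
    missing part of the 37-gene complement only warns.
    """
    feats = [f for f in sorted(g.features, key=lambda f: (f.start, f.end))
             if not f.flagged]
    labels = [f.label for f in feats]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen and not is_ncr_label(lab):
            raise ValueError(f"duplicate gene label {lab}")
        seen.add(lab)
    missing = {lab for lab, _ in ANCESTRAL_ORDER} - seen - {"CR"}
    if missing:
        warnings.warn(f"{g.accession}: missing genes {sorted(missing)}")
    return GeneOrder(tuple((f.label, +1 if f.strand == "J" else -1) for f in feats))


def normalize_rotation(o: GeneOrder, anchor: str) -> GeneOrder:
    """Rotate so ``anchor`` comes first (deterministic, idempotent)."""
    if anchor not in o.labels:
        raise ValueError(f"anchor {anchor} absent from order")
    i = o.index(anchor)
    return GeneOrder(o.elements[i:] + o.elements[:i])


def _adjacency_set(o: GeneOrder) -> set[frozenset[str]]:
    labs = o.without_ncr().labels
    n = len(labs)
    return {frozenset((labs[i], labs[(i + 1) % n])) for i in range(n)}


def breakpoint_distance(ref: GeneOrder, obs: GeneOrder) -> int:
    """Number of circular unsigned gene adjacencies of ``ref`` absent
    from ``obs`` (NCR elements ignored).  Symmetric and
    rotation-invariant; zero iff the unsigned orders are rotation-equal.
    """
    a, b = ref.without_ncr(), obs.without_ncr()
    if set(a.labels) != set(b.labels):
        raise ValueError("breakpoint distance requires identical label sets")
    return len(_adjacency_set(a) - _adjacency_set(b))


def _rotation_equal(a: Sequence[SignedLabel], b: Sequence[SignedLabel]) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    ta, tb = tuple(a), tuple(b)
    return any(tb[i:] + tb[:i] == ta for i in range(len(tb)))


def moved_genes(ref: GeneOrder, obs: GeneOrder, max_moved: int = 5) -> list[frozenset[str]]:
    """All minimal sets of genes whose removal makes the two circular
    orders identical as rotations (signs respected).

    The complement of each returned set is a maximum-length circular
    common subsequence.  Exhaustive search, adequate because observed
    mitogenome rearrangements move very few genes; raises if more than
    ``max_moved`` moves would be needed.
    """
    a, b = ref.without_ncr(), obs.without_ncr()
    if set(a.labels) != set(b.labels):
        raise ValueError("moved_genes requires identical label sets")
    labels = a.labels
    for k in range(0, max_moved + 1):
        optima = []
        for removal in itertools.combinations(labels, k):
            rs = set(removal)
            ra = [e for e in a.elements if e[0] not in rs]
            rb = [e for e in b.elements if e[0] not in rs]
            if _rotation_equal(ra, rb):
                optima.append(frozenset(removal))
        if optima:
            return optima
    raise ValueError(f"orders differ by more than {max_moved} moved genes")


# ---------------------------------------------------------------------------
# TDRL enumeration

@dataclass(frozen=True)
class TDRLScenario:
    """One duplication block plus per-gene copy-loss assignment.

    ``block`` is the (i, j) inclusive index span of the duplicated
    source window; ``lost_copy`` maps every duplicated gene to the copy
    (1 or 2) that decayed.  ``remnant_slots`` lists, per NCR present in
    the target window, the lost copies flanked by the same kept
    neighbours as that NCR -- the candidate origins of the non-coding
    remnant.
    """

    source: tuple[SignedLabel, ...]
    block: tuple[int, int]
    lost_copy: tuple[tuple[str, int], ...]  # (label, lost copy index)
    result: tuple[SignedLabel, ...]
    remnant_slots: tuple[tuple[int, tuple[tuple[str, int], ...]], ...] = ()

    def reapply(self) -> tuple[SignedLabel, ...]:
        return apply_tdrl(self.source, self.block, dict(self.lost_copy))


def apply_tdrl(
    source: Sequence[SignedLabel],
    block: tuple[int, int],
    lost_copy: dict[str, int],
) -> tuple[SignedLabel, ...]:
    """Duplicate ``source[block]`` in tandem, then delete the assigned
    copy of every duplicated gene; returns the resulting linear order."""
    i, j = block
    dup = list(source[: j + 1]) + list(source[i:])
    # copy index per position: block occurs at i..j (copy 1) and j+1..2j-i+1 (copy 2)
    out = []
    for pos, el in enumerate(dup):
        if i <= pos <= j:
            copy = 1
        elif j < pos <= 2 * j - i + 1:
            copy = 2
        else:
            copy = 0
        if copy and lost_copy.get(el[0]) == copy:
            continue
        out.append(el)
    return tuple(out)


def _remnant_slots(
    source: Sequence[SignedLabel],
    block: tuple[int, int],
    lost_copy: dict[str, int],
    target: Sequence[SignedLabel],
) -> tuple[tuple[int, tuple[tuple[str, int], ...]], ...]:
    """Match lost copies to NCR positions of the target window by their
    flanking kept genes."""
    i, j = block
    dup: list[tuple[SignedLabel, int]] = []
    for pos, el in enumerate(list(source[: j + 1]) + list(source[i:])):
        if i <= pos <= j:
            copy = 1
        elif j < pos <= 2 * j - i + 1:
            copy = 2
        else:
            copy = 0
        dup.append((el, copy))
    # neighbours of each lost copy among kept elements
    lost_between: list[tuple[str | None, str | None, str, int]] = []
    kept_labels = [el[0] for el, c in dup if not (c and lost_copy.get(el[0]) == c)]
    left: str | None = None
    pending: list[tuple[str, int]] = []
    gaps: dict[tuple[str | None, str | None], list[tuple[str, int]]] = {}
    for el, c in dup:
        lost = c and lost_copy.get(el[0]) == c
        if lost:
            pending.append((el[0], c))
        else:
            if pending:
                gaps.setdefault((left, el[0]), []).extend(pending)
                pending = []
            left = el[0]
    if pending:
        gaps.setdefault((left, None), []).extend(pending)
    # NCR positions in target with their kept flanks
    slots = []
    for idx, el in enumerate(target):
        if not is_ncr_label(el[0]):
            continue
        lf = next((target[k][0] for k in range(idx - 1, -1, -1)
                   if not is_ncr_label(target[k][0])), None)
        rt = next((target[k][0] for k in range(idx + 1, len(target))
                   if not is_ncr_label(target[k][0])), None)
        slots.append((idx, tuple(gaps.get((lf, rt), []))))
    return tuple(slots)


def enumerate_single_tdrl(
    source: GeneOrder | Sequence[SignedLabel],
    target: GeneOrder | Sequence[SignedLabel],
    max_window: int = 12,
) -> list[TDRLScenario]:
    """All single-TDRL scenarios turning the linear window ``source``
    into ``target``.

    Exhaustive over every contiguous block and every copy-loss
    assignment (2^block scenarios per block).  NCR elements of the
    target are ignored for order comparison but drive the remnant-slot
    bookkeeping.  Returns [] when any gene's strand differs between the
    windows: a single TDRL never inverts.
    """
    src = tuple(source.elements if isinstance(source, GeneOrder) else source)
    tgt = tuple(target.elements if isinstance(target, GeneOrder) else target)
    src = tuple(e for e in src if not is_ncr_label(e[0]))
    tgt_genes = tuple(e for e in tgt if not is_ncr_label(e[0]))
    if len(src) > max_window:
        raise ValueError(f"window of {len(src)} exceeds cap {max_window}")
    if sorted(e[0] for e in src) != sorted(e[0] for e in tgt_genes):
        raise ValueError("windows must share their gene label set")
    if set(src) != set(tgt_genes):  # sign change somewhere
        return []
    n = len(src)
    scenarios: list[TDRLScenario] = []
    for i in range(n):
        for j in range(i, n):
            block_labels = [e[0] for e in src[i: j + 1]]
            for losses in itertools.product((1, 2), repeat=j - i + 1):
                lost = dict(zip(block_labels, losses))
                result = apply_tdrl(src, (i, j), lost)
                if result == tgt_genes:
                    scenarios.append(TDRLScenario(
                        source=src, block=(i, j),
                        lost_copy=tuple(sorted(lost.items())),
                        result=result,
                        remnant_slots=_remnant_slots(src, (i, j), lost, tgt),
                    ))
    return scenarios


def classify_ncr(length: int) -> str:
    """Class of a non-coding region by length: NCR1 (<100 bp), NCR2
    (>400 bp), or 'intermediate' for the 100-400 bp range outside the
    observed dichotomy."""
    if length < 1:
        raise ValueError("NCR length must be positive")
    if length < 100:
        return "NCR1"
    if length > 400:
        return "NCR2"
    return "intermediate"


# ---------------------------------------------------------------------------
# classification

@dataclass
class RearrangementReport:
    breakpoint_count: int
    moved: list[frozenset[str]] = field(default_factory=list)
    event_class: str = "none"  # none/translocation/inversion/complex
    tdrl_compatible: bool = False
    scenarios: list[TDRLScenario] = field(default_factory=list)
    ncrs: list[tuple[int, int, str]] = field(default_factory=list)  # (position, length, class)

    @property
    def moved_genes(self) -> frozenset[str]:
        return frozenset().union(*self.moved) if self.moved else frozenset()

    def to_dict(self) -> dict:
        return {
            "breakpoint_count": self.breakpoint_count,
            "moved_gene_sets": [sorted(s) for s in self.moved],
            "event_class": self.event_class,
            "tdrl_compatible": self.tdrl_compatible,
            "n_scenarios": len(self.scenarios),
            "scenarios": [
                {
                    "block": list(s.block),
                    "block_genes": [lab for lab, _ in s.source[s.block[0]: s.block[1] + 1]],
                    "lost_copy": {lab: c for lab, c in s.lost_copy},
                    "result": [_fmt_signed(e) for e in s.result],
                    "remnant_candidates": [
                        {"ncr_index": idx, "lost_copies": [list(x) for x in cands]}
                        for idx, cands in s.remnant_slots],
                }
                for s in self.scenarios
            ],
            "ncrs": [{"position": p, "length": ln, "class": cl}
                     for p, ln, cl in self.ncrs],
        }


def _tdrl_windows(
    ref: GeneOrder, obs: GeneOrder
) -> tuple[tuple[SignedLabel, ...], tuple[SignedLabel, ...]] | None:
    """Breakpoint-bounded windows: the minimal circular arc of ``ref``
    covering every broken adjacency, and the matching arc of ``obs``
    (NCRs included)."""
    a, b = ref.without_ncr(), obs.without_ncr()
    broken = _adjacency_set(a) - _adjacency_set(b)
    if not broken:
        return None
    n = len(a)
    # edges (i, i+1) of ref that are broken
    edge_pos = [i for i in range(n)
                if frozenset((a.labels[i], a.labels[(i + 1) % n])) in broken]
    # minimal circular arc containing all broken edges = complement of
    # the largest gap between consecutive broken edges
    edge_pos.sort()
    if len(edge_pos) == n:
        return None  # everything broken; no useful window
    gaps = []
    for k in range(len(edge_pos)):
        nxt = edge_pos[(k + 1) % len(edge_pos)]
        gap = (nxt - edge_pos[k]) % n
        gaps.append((gap, k))
    _, k0 = max(gaps)
    first_edge = edge_pos[(k0 + 1) % len(edge_pos)]
    last_edge = edge_pos[k0]
    start = first_edge
    span = (last_edge - first_edge) % n + 2  # include both endpoints of last edge
    if span > n:
        return None
    src = tuple(a.elements[(start + t) % n] for t in range(span))
    # matching arc in obs: minimal circular arc covering the same labels
    want = {lab for lab, _ in src}
    m = len(obs)
    pos = [i for i, (lab, _) in enumerate(obs.elements) if lab in want]
    if not pos:
        return None
    gaps2 = []
    for k in range(len(pos)):
        nxt = pos[(k + 1) % len(pos)]
        gaps2.append((((nxt - pos[k]) % m), k))
    _, k1 = max(gaps2)
    o_start = pos[(k1 + 1) % len(pos)]
    o_end = pos[k1]
    o_span = (o_end - o_start) % m + 1
    tgt = tuple(obs.elements[(o_start + t) % m] for t in range(o_span))
    if {lab for lab, _ in tgt if not is_ncr_label(lab)} != want:
        return None  # extra genes interleaved; not a clean window
    return src, tgt


def classify_rearrangement(
    ref: GeneOrder,
    obs: GeneOrder,
    ncr_lengths: dict[str, int] | None = None,
    max_window: int = 12,
) -> RearrangementReport:
    """Compare an observed order against a reference.

    Event classes: ``none`` (rotation-equal), ``inversion`` (same
    unsigned order, some signs flipped in place), ``translocation``
    (moved genes keep their strand), ``complex`` otherwise.  For
    sign-preserving events the breakpoint-bounded window is searched
    exhaustively for single-TDRL scenarios; finding any sets
    ``tdrl_compatible``.
    """
    ncr_lengths = ncr_lengths or {}
    report = RearrangementReport(breakpoint_count=breakpoint_distance(ref, obs))
    for idx, (lab, _) in enumerate(obs.elements):
        if is_ncr_label(lab):
            ln = ncr_lengths.get(lab, 0)
            report.ncrs.append((idx, ln, classify_ncr(ln) if ln >= 1 else "unknown"))

    a, b = ref.without_ncr(), obs.without_ncr()
    signed_equal = a == b
    unsigned_equal = _rotation_equal(
        [(lab, 0) for lab, _ in a.elements], [(lab, 0) for lab, _ in b.elements])
    if signed_equal and report.breakpoint_count == 0:
        report.event_class = "none"
        return report
    if unsigned_equal and not signed_equal:
        sa = dict(a.elements)
        report.event_class = "inversion"
        flipped = frozenset(lab for lab, sg in b.elements if sa[lab] != sg)
        report.moved = [flipped]
        return report

    try:
        report.moved = moved_genes(ref, obs)
    except ValueError:
        report.event_class = "complex"
        return report
    sa, sb = dict(a.elements), dict(b.elements)
    sign_preserved = any(all(sa[lab] == sb[lab] for lab in opt) for opt in report.moved)
    report.event_class = "translocation" if sign_preserved else "complex"
    if sign_preserved:
        windows = _tdrl_windows(ref, obs)
        if windows and len([e for e in windows[0]]) <= max_window:
            scenarios = enumerate_single_tdrl(windows[0], windows[1], max_window)
            report.scenarios = scenarios
            report.tdrl_compatible = bool(scenarios)
    return report
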