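"""Synthetic annotated mitogenomes with known ground truth.

The generator emits a 37-gene circular insect mitogenome (13 PCGs,
22 tRNAs, 2 rRNAs, one control region) in either the ancestral
trnI-trnQ-trnM arrangement or the rearranged trnQ-NCR-trnI-trnM
arrangement, together with a :class:`GroundTruth` record describing
every observable a downstream analysis should recover: the gene order,
per-PCG start/stop codons and offsets, spacer and overlap geometry,
planted motifs and homopolymer runs, the control-region tandem repeat
and the NCR bounds.

Sequence content is random but composition-controlled: non-coding
background is laid down with exact (largest-remainder rounded) base
counts for the requested AT fraction and AT/GC skews, and PCG bodies are
drawn codon-wise from sense codons with base weights tilted so that the
conditional (stop-free) composition matches the same targets.  Content
for genes on the minority strand is generated against the complemented
targets so the genome-forward composition is homogeneous.  tRNA and
rRNA bodies are plain background: cloverleaf structure is out of scope.

One integer seed drives every draw through a single numpy Generator, so
a fixed spec is byte-reproducible, and varying only the seed changes
sequence content but never the annotation geometry.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .codon_usage import SENSE_CODONS, STOP_CODONS
from .genes import (
    ANCESTRAL_ORDER, CR, J, N, NCR, PCGS, REARRANGED_IQ_ORDER,
    category_of, revcomp,
)
from .mito_io import GeneFeature, Mitogenome, write_genbank

__all__ = [
    "SyntheticSpec", "SpacerSpec", "GroundTruth", "generate",
    "compose_region_sequence", "build_pcg",
    "cetoniinae_like", "dynastinae_like", "write_outputs",
]

BASES = ("A", "C", "G", "T")

# codon count includes the start codon, excludes the stop
DEFAULT_PCG_CODONS: dict[str, int] = {
    "ND2": 340, "COX1": 512, "COX2": 227, "COX3": 261, "ATP8": 51,
    "ATP6": 224, "ND3": 117, "ND5": 571, "ND4": 443, "ND4L": 95,
    "ND6": 165, "CYTB": 378, "ND1": 315,
}

# start/stop choices modelled on cetoniine beetles: COX1 opens with the
# atypical asparagine codon AAC one base after the upstream tRNA, and
# the three cytochrome oxidase subunits end on the incomplete stop T.
CETONIINE_STARTS = {
    "ND2": "ATT", "COX1": "AAC", "COX2": "ATT", "COX3": "ATC",
    "ATP8": "ATG", "ATP6": "ATG", "ND3": "ATT", "ND5": "ATT",
    "ND4": "ATG", "ND4L": "ATG", "ND6": "ATT", "CYTB": "ATG", "ND1": "ATT",
}
CETONIINE_STOPS = {
    "ND2": "TAG", "COX1": "T", "COX2": "T", "COX3": "T",
    "ATP8": "TAA", "ATP6": "TAA", "ND3": "TAG", "ND5": "TAA",
    "ND4": "T", "ND4L": "TAA", "ND6": "TAA", "CYTB": "TAG", "ND1": "TAA",
}
# dynastine-style choices: canonical ATN throughout, ND5 with incomplete T
DYNASTINE_STARTS = {
    "ND2": "ATT", "COX1": "ATT", "COX2": "ATT", "COX3": "ATC",
    "ATP8": "ATG", "ATP6": "ATG", "ND3": "ATC", "ND5": "ATT",
    "ND4": "ATG", "ND4L": "ATG", "ND6": "ATT", "CYTB": "ATG", "ND1": "ATT",
}
DYNASTINE_STOPS = {
    "ND2": "TAA", "COX1": "T", "COX2": "T", "COX3": "T",
    "ATP8": "TAA", "ATP6": "TAA", "ND3": "TAG", "ND5": "T",
    "ND4": "TAA", "ND4L": "TAA", "ND6": "TAA", "CYTB": "TAG", "ND1": "TAA",
}

STOP_LEN = {"TAA": 3, "TAG": 3, "TA": 2, "T": 1}


@dataclass(frozen=True)
class SpacerSpec:
    """A designed intergenic spacer between a genome-adjacent pair."""

    length: int
    motif: str | None = None
    motif_offset: int | None = None  # default: centered
    homopolymer: tuple[str, int] | None = None  # (base, run length)


@dataclass
class SyntheticSpec:
    """Everything needed to build one synthetic mitogenome."""

    template: str = "ancestral"  # "ancestral" or "rearranged"
    seed: int = 0
    at_fraction: float = 0.72
    skew_at: float = 0.05
    skew_gc: float = -0.15
    pcg_codons: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PCG_CODONS))
    start_codons: dict[str, str] = field(default_factory=lambda: dict(CETONIINE_STARTS))
    stop_codons: dict[str, str] = field(default_factory=lambda: dict(CETONIINE_STOPS))
    trna_length: int = 65
    rrns_length: int = 780
    rrnl_length: int = 1280
    cr_length: int = 1776
    cr_at_fraction: float = 0.85
    cr_repeat: tuple[int, int] | None = (57, 4)  # (unit bp, copies)
    ncr_length: int = 56  # used by the rearranged template only
    overlaps: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("trnW", "trnC"): 8})
    spacers: dict[tuple[str, str], SpacerSpec] = field(default_factory=dict)

    def order(self) -> tuple[tuple[str, int], ...]:
        if self.template == "ancestral":
            return ANCESTRAL_ORDER
        if self.template == "rearranged":
            return REARRANGED_IQ_ORDER
        raise ValueError(f"unknown template {self.template!r}")

    def element_length(self, label: str) -> int:
        if label in PCGS:
            return 3 * self.pcg_codons[label] + STOP_LEN[self.stop_codons[label]]
        if label.startswith("trn"):
            return self.trna_length
        if label == "rrnS":
            return self.rrns_length
        if label == "rrnL":
            return self.rrnl_length
        if label == CR:
            return self.cr_length
        if label == NCR:
            return self.ncr_length
        raise KeyError(label)

    def validate(self) -> None:
        if not (0.0 <= self.at_fraction <= 1.0):
            raise ValueError("AT fraction must lie in [0,1]")
        for s in (self.skew_at, self.skew_gc):
            if abs(s) > 1:
                raise ValueError("skews must lie in [-1,1]")
        for pcg, stop in self.stop_codons.items():
            if stop not in STOP_LEN:
                raise ValueError(f"{pcg}: unsupported stop {stop}")
        for lab, n in self.pcg_codons.items():
            if n < 2:
                raise ValueError(f"{lab}: needs at least start + one body codon")
        order_labels = [lab for lab, _ in self.order()]
        for (a, b), bp in self.overlaps.items():
            ia = order_labels.index(a)
            if order_labels[(ia + 1) % len(order_labels)] != b:
                raise ValueError(f"overlap pair {a}/{b} not adjacent in template")
            if bp >= min(self.element_length(a), self.element_length(b)):
                raise ValueError(f"overlap {a}/{b} longer than a participating gene")
            if (a, b) in self.spacers:
                raise ValueError(f"{a}/{b} cannot both overlap and have a spacer")
        if self.cr_repeat is not None:
            u, k = self.cr_repeat
            if u < 2 or k < 2 or u * k + 16 > self.cr_length:
                raise ValueError("control-region repeat does not fit")


# ---------------------------------------------------------------------------
# composition-controlled sequence synthesis

def base_probabilities(at: float, skew_at: float, skew_gc: float) -> np.ndarray:
    """(pA, pC, pG, pT) realizing the AT fraction and both skews."""
    p = np.array([
        at * (1 + skew_at) / 2,
        (1 - at) * (1 - skew_gc) / 2,
        (1 - at) * (1 + skew_gc) / 2,
        at * (1 - skew_at) / 2,
    ])
    if (p < -1e-12).any():
        raise ValueError("infeasible composition targets")
    return np.clip(p, 0, 1)


def compose_region_sequence(
    length: int,
    at: float,
    skew_at: float,
    skew_gc: float,
    rng: np.random.Generator,
) -> str:
    """Background sequence hitting the composition targets.

    Base counts are fixed by largest-remainder rounding of the target
    probabilities and then shuffled, so the realized composition of each
    region deviates from its target only by rounding, not by sampling.
    """
    if length == 0:
        return ""
    p = base_probabilities(at, skew_at, skew_gc)
    raw = p * length
    counts = np.floor(raw).astype(int)
    short = length - counts.sum()
    for idx in np.argsort(-(raw - counts))[:short]:
        counts[idx] += 1
    arr = np.repeat(np.array(list("ACGT")), counts)
    rng.shuffle(arr)
    return "".join(arr)


def _tilted_codon_weights(p: np.ndarray, iters: int = 200) -> dict[str, float]:
    """Sense-codon weights whose expected base composition equals ``p``.

    Drawing codons as independent bases conditioned on not being a stop
    codon depletes A/T slightly (TAA/TAG are A+T rich); a fixed-point
    tilt of the base weights corrects for that exactly in expectation.
    """
    base_idx = {b: i for i, b in enumerate(BASES)}
    q = p.copy()
    for _ in range(iters):
        w = np.array([q[base_idx[c[0]]] * q[base_idx[c[1]]] * q[base_idx[c[2]]]
                      for c in SENSE_CODONS])
        if w.sum() == 0:
            raise ValueError("degenerate codon weights")
        w /= w.sum()
        comp = np.zeros(4)
        for wi, c in zip(w, SENSE_CODONS):
            for ch in c:
                comp[base_idx[ch]] += wi / 3
        ratio = np.divide(p, comp, out=np.ones(4), where=comp > 0)
        q = q * ratio
        q /= q.sum()
    w = np.array([q[base_idx[c[0]]] * q[base_idx[c[1]]] * q[base_idx[c[2]]]
                  for c in SENSE_CODONS])
    w /= w.sum()
    return dict(zip(SENSE_CODONS, w))


def build_pcg(
    length_codons: int,
    start_codon: str,
    stop_codon: str,
    codon_weights: Mapping[str, float],
    rng: np.random.Generator,
) -> str:
    """A PCG in reading orientation: start codon, ``length_codons`` body
    codons drawn from sense codons by weight (never an in-frame stop),
    then the terminal stop, possibly incomplete (TA or T)."""
    if stop_codon not in STOP_LEN:
        raise ValueError(f"unsupported stop codon {stop_codon}")
    codons = list(codon_weights)
    w = np.array([codon_weights[c] for c in codons], dtype=float)
    if w.sum() <= 0:
        raise ValueError("codon weights sum to zero")
    w /= w.sum()
    # quota sampling: per-codon counts fixed by largest-remainder rounding
    # of the weights, then shuffled -- keeps the realized composition at
    # its expectation instead of adding multinomial noise
    raw = w * length_codons
    counts = np.floor(raw).astype(int)
    for idx in np.argsort(-(raw - counts))[: length_codons - counts.sum()]:
        counts[idx] += 1
    body = np.repeat(np.arange(len(codons)), counts)
    rng.shuffle(body)
    return start_codon + "".join(codons[i] for i in body) + stop_codon


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class GroundTruth:
    """Construction record of a synthetic genome, for round-trip tests."""

    seed: int
    template: str
    gene_order: list[str]  # signed tokens, genome order
    features: dict[str, dict]
    starts: dict[str, dict]  # pcg -> {codon, offset}
    stops: dict[str, str]
    spacers: list[dict]
    overlaps: list[dict]
    motifs: list[dict]
    homopolymers: list[dict]
    cr: dict
    cr_repeat: dict | None
    ncr: dict | None
    targets: dict

    def to_json(self, **kw) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, **kw)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# generation

def _spacer_content(spec_sp: SpacerSpec, at: float, s_at: float, s_gc: float,
                    rng: np.random.Generator) -> tuple[str, dict]:
    """Spacer sequence with the designed motif / homopolymer planted
    exactly once; resamples (deterministically) until clean."""
    from .region_scan import find_motif, homopolymer_runs

    n = spec_sp.length
    for _ in range(200):
        seq = compose_region_sequence(n, at, s_at, s_gc, rng)
        meta: dict = {}
        if spec_sp.motif:
            m = spec_sp.motif
            off = spec_sp.motif_offset
            if off is None:
                off = (n - len(m)) // 2
            seq = seq[:off] + m + seq[off + len(m):]
            if find_motif(seq, m) != [off]:
                continue
            meta["motif"] = m
            meta["offset"] = off
        if spec_sp.homopolymer:
            base, run = spec_sp.homopolymer
            off = (n - run) // 2
            seq = seq[:off] + base * run + seq[off + run:]
            # guard bases so the planted run is maximal
            others = [b for b in BASES if b != base]
            if off > 0 and seq[off - 1] == base:
                seq = seq[:off - 1] + str(rng.choice(others)) + seq[off:]
            end = off + run
            if end < n and seq[end] == base:
                seq = seq[:end] + str(rng.choice(others)) + seq[end + 1:]
            if homopolymer_runs(seq, min_len=max(2, run // 2)) != [(base, off, run)]:
                continue
            meta["homopolymer"] = [base, run]
            meta["offset"] = off
        return seq, meta
    raise RuntimeError("could not realize spacer constraints")


def _cr_content(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[str, dict | None]:
    """Control region: a tandem-repeat array near its 5' end, then an
    A+T-rich subregion."""
    n = spec.cr_length
    at, s_at, s_gc = spec.cr_at_fraction, spec.skew_at, spec.skew_gc
    if spec.cr_repeat is None:
        return compose_region_sequence(n, at, s_at, s_gc, rng), None
    u, k = spec.cr_repeat
    pad = 8
    from .region_scan import _smallest_period

    for _ in range(200):
        unit = compose_region_sequence(u, at, s_at, s_gc, rng)
        if _smallest_period(unit) != u:
            continue
        head = compose_region_sequence(pad, at, s_at, s_gc, rng)
        tail = compose_region_sequence(n - pad - u * k, at, s_at, s_gc, rng)
        # maximality guards
        others_l = [b for b in BASES if b != unit[-1]]
        others_r = [b for b in BASES if b != unit[0]]
        if head[-1] == unit[-1]:
            head = head[:-1] + str(rng.choice(others_l))
        if tail and tail[0] == unit[0]:
            tail = str(rng.choice(others_r)) + tail[1:]
        seq = head + unit * k + tail
        return seq, {"unit_sequence": unit, "unit_length": u,
                     "copies": float(k), "offset": pad}
    raise RuntimeError("could not realize control-region repeat")


def _default_spacers(spec: SyntheticSpec) -> dict[tuple[str, str], SpacerSpec]:
    """Template spacers merged with user overrides."""
    sp: dict[tuple[str, str], SpacerSpec] = {}
    if spec.template == "ancestral":
        # one-base gap before COX1 puts the AAC start at offset 1 while the
        # nearest canonical candidate sits farther away, as in cetoniines
        if spec.start_codons.get("COX1") in ("AAC", "AAT"):
            sp[("trnY", "COX1")] = SpacerSpec(length=1)
        sp[("trnS2", "ND1")] = SpacerSpec(length=18, motif="TACTAA")
    else:
        sp[("trnS2", "ND1")] = SpacerSpec(length=20, motif="TACTA")
        sp[("trnK", "trnD")] = SpacerSpec(length=20, homopolymer=("C", 11))
    sp.update(spec.spacers)
    return sp


def generate(spec: SyntheticSpec) -> tuple[Mitogenome, GroundTruth]:
    """Build the genome and its ground truth.  Deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    order = spec.order()
    spacers = _default_spacers(spec)
    at, s_at, s_gc = spec.at_fraction, spec.skew_at, spec.skew_gc
    p_fwd = base_probabilities(at, s_at, s_gc)
    p_rev = p_fwd[::-1]  # complement: A<->T, C<->G swap
    weights_fwd = _tilted_codon_weights(p_fwd)
    weights_rev = _tilted_codon_weights(p_rev)

    parts: list[str] = []
    feats: list[GeneFeature] = []
    gt_spacers: list[dict] = []
    gt_overlaps: list[dict] = []
    gt_motifs: list[dict] = []
    gt_homop: list[dict] = []
    gt_starts: dict[str, dict] = {}
    cr_repeat_gt: dict | None = None
    cr_span = ncr_span = None
    cursor = 0
    prev_label: str | None = None

    for label, sign in order:
        strand = J if sign > 0 else N
        pair = (prev_label, label) if prev_label else None
        overlap = spec.overlaps.get(pair, 0) if pair else 0
        if pair and pair in spacers:
            sp = spacers[pair]
            seq_sp, meta = _spacer_content(sp, at, s_at, s_gc, rng)
            parts.append(seq_sp)
            gt_spacers.append({"upstream": pair[0], "downstream": pair[1],
                               "length": sp.length})
            if "motif" in meta:
                gt_motifs.append({"upstream": pair[0], "downstream": pair[1],
                                  "motif": meta["motif"],
                                  "offset": meta["offset"],
                                  "position": cursor + meta["offset"]})
            if "homopolymer" in meta:
                base, run = meta["homopolymer"]
                gt_homop.append({"upstream": pair[0], "downstream": pair[1],
                                 "base": base, "length": run,
                                 "position": cursor + meta["offset"]})
            cursor += sp.length
        elif pair and not overlap:
            gt_spacers.append({"upstream": pair[0], "downstream": pair[1],
                               "length": 0})

        if label in PCGS:
            weights = weights_fwd if strand == J else weights_rev
            reading = build_pcg(spec.pcg_codons[label] - 1,
                                spec.start_codons[label],
                                spec.stop_codons[label], weights, rng)
            content = revcomp(reading) if strand == N else reading
            offset = spacers.get(pair, SpacerSpec(0)).length if pair in spacers else 0
            # start offset in reading orientation: J genes take the spacer
            # placed immediately before them in genome order; N genes abut
            # their reading-upstream neighbour by construction
            gt_starts[label] = {
                "codon": spec.start_codons[label],
                "offset": offset if strand == J else 0,
            }
        elif label == CR:
            content, cr_repeat_gt = _cr_content(spec, rng)
            if cr_repeat_gt is not None:
                cr_repeat_gt = dict(cr_repeat_gt,
                                    start=cursor + cr_repeat_gt.pop("offset"))
        else:
            n = spec.element_length(label)
            content = compose_region_sequence(n - overlap, at, s_at, s_gc, rng)
            # with an overlap the leading bases are shared with the
            # previous gene; only the novel tail is appended

        start = cursor - overlap
        length = spec.element_length(label)
        if overlap:
            gt_overlaps.append({"upstream": prev_label, "downstream": label,
                                "length": overlap})
            parts.append(content if label not in PCGS else content[overlap:])
        else:
            parts.append(content)
        feats.append(GeneFeature(label=label, category=category_of(label),
                                 strand=strand, start=start, end=start + length))
        if label == CR:
            cr_span = (start, start + length)
        if label == NCR:
            ncr_span = (start, start + length)
        cursor = start + length
        prev_label = label

    sequence = "".join(parts)
    assert len(sequence) == cursor, "layout bookkeeping broke"
    genome = Mitogenome(
        accession=f"SYN{spec.seed:06d}",
        organism=f"Synthetica {spec.template} (synthetic)",
        topology="circular",
        sequence=sequence,
        features=feats,
    )
    gt = GroundTruth(
        seed=spec.seed,
        template=spec.template,
        gene_order=[("-" if sign < 0 else "") + lab for lab, sign in order],
        features={f.label: {"start": f.start, "end": f.end, "strand": f.strand,
                            "category": f.category} for f in feats},
        starts=gt_starts,
        stops=dict(spec.stop_codons),
        spacers=gt_spacers,
        overlaps=gt_overlaps,
        motifs=gt_motifs,
        homopolymers=gt_homop,
        cr={"start": cr_span[0], "end": cr_span[1], "length": cr_span[1] - cr_span[0]},
        cr_repeat=cr_repeat_gt,
        ncr=(None if ncr_span is None else
             {"start": ncr_span[0], "end": ncr_span[1],
              "length": ncr_span[1] - ncr_span[0]}),
        targets={"at_fraction": at, "skew_at": s_at, "skew_gc": s_gc,
                 "cr_at_fraction": spec.cr_at_fraction,
                 # whole-genome expectation: every region is laid down at the
                 # background targets except the A+T-enriched control region
                 "expected_at_fraction":
                     (at * (cursor - spec.cr_length)
                      + spec.cr_at_fraction * spec.cr_length) / cursor},
    )
    return genome, gt


def cetoniinae_like(seed: int = 0, **overrides) -> SyntheticSpec:
    """Ancestral gene order, AAC start for COX1 one base downstream of
    trnY, TACTAA motif in the trnS2-ND1 spacer."""
    return SyntheticSpec(template="ancestral", seed=seed, **overrides)


def dynastinae_like(seed: int = 0, ncr_length: int = 56, **overrides) -> SyntheticSpec:
    """Rearranged trnQ-NCR-trnI-trnM order with an NCR of 56 bp (or
    412 bp for the long variant), TACTA motif in the trnS2-ND1 spacer
    and an 11 bp C-stretch in the trnK-trnD spacer."""
    overrides.setdefault("start_codons", dict(DYNASTINE_STARTS))
    overrides.setdefault("stop_codons", dict(DYNASTINE_STOPS))
    return SyntheticSpec(template="rearranged", seed=seed,
                         ncr_length=ncr_length, **overrides)


def spec_from_file(path: str | Path) -> SyntheticSpec:
    """Load a :class:`SyntheticSpec` from YAML (or JSON, a YAML subset).

    ``overlaps`` and ``spacers`` keys are written ``"upstream,downstream"``;
    spacer values are mappings of :class:`SpacerSpec` fields.
    """
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    if "overlaps" in data:
        data["overlaps"] = {tuple(k.split(",")): v
                            for k, v in data["overlaps"].items()}
    if "spacers" in data:
        data["spacers"] = {
            tuple(k.split(",")): SpacerSpec(
                **{**v, "homopolymer": tuple(v["homopolymer"])
                   if v.get("homopolymer") else None})
            for k, v in data["spacers"].items()}
    if "cr_repeat" in data and data["cr_repeat"] is not None:
        data["cr_repeat"] = tuple(data["cr_repeat"])
    for key in ("pcg_codons", "start_codons", "stop_codons"):
        if key in data:
            base = dict(DEFAULT_PCG_CODONS if key == "pcg_codons" else
                        CETONIINE_STARTS if key == "start_codons" else
                        CETONIINE_STOPS)
            base.update(data[key])
            data[key] = base
    return SyntheticSpec(**data)


def write_outputs(genome: Mitogenome, gt: GroundTruth, outdir: str | Path) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gb = outdir / f"{genome.accession}.gb"
    write_genbank([genome], gb)
    gtp = outdir / f"{genome.accession}.ground_truth.json"
    gtp.write_text(gt.to_json())
    return gb, gtp
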