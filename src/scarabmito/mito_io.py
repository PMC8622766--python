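"""Read/write annotated circular mitogenomes and canonicalize gene naming.

Internal coordinates are 0-based half-open.  A feature that spans the
origin of the circular molecule is encoded with ``end > genome length``
and interpreted modulo the length, so one biological gene is always one
feature.  All user-facing tables use the familiar 1-based inclusive
GenBank convention.

Strands are named ``J`` (the forward strand of the deposited sequence,
the majority coding strand) and ``N`` (its complement).
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .genes import (
    CANONICAL_GENES, COMPLEMENT, CR, J, N, NCR, PCGS, RRNAS, TRNAS,
    category_of, revcomp,
)

__all__ = [
    "GeneFeature", "Mitogenome", "canonical_gene_name", "read_genbank",
    "write_genbank", "read_fasta", "extract_gene_sequence",
    "write_feature_table", "read_feature_table",
]

UNKNOWN_PREFIX = "unknown:"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene/region on the circular molecule.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``end`` may exceed
    the genome length for an origin-spanning feature.
    """

    label: str
    category: str
    strand: str  # J or N
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.label}: end must exceed start")
        if self.strand not in (J, N):
            raise ValueError(f"{self.label}: strand must be J or N")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def flagged(self) -> bool:
        return self.label.startswith(UNKNOWN_PREFIX)


@dataclass
class Mitogenome:
    """A circular annotated DNA record: sequence plus ordered features."""

    accession: str
    organism: str
    topology: str  # "circular" or "linear"
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        L = len(self.sequence)
        for f in self.features:
            if not 0 <= f.start < L:
                raise ValueError(f"{f.label}: start {f.start} outside [0,{L})")
            if f.length > L:
                raise ValueError(f"{f.label}: span exceeds genome length")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        dup = _duplicate_canonical(self.features)
        if dup:
            self.warnings.append(f"duplicate canonical labels: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, label: str) -> GeneFeature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(label)

    def canonical_features(self) -> list[GeneFeature]:
        """Features with canonical (non-flagged) labels."""
        return [f for f in self.features if not f.flagged]


def _duplicate_canonical(features: Sequence[GeneFeature]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for f in features:
        if f.label in CANONICAL_GENES:
            if f.label in seen:
                dup.add(f.label)
            seen.add(f.label)
    return dup


# ---------------------------------------------------------------------------
# gene-name canonicalization

_AA3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}

_PCG_PRODUCTS = {
    "ND1": "NADH dehydrogenase subunit 1",
    "ND2": "NADH dehydrogenase subunit 2",
    "ND3": "NADH dehydrogenase subunit 3",
    "ND4": "NADH dehydrogenase subunit 4",
    "ND4L": "NADH dehydrogenase subunit 4L",
    "ND5": "NADH dehydrogenase subunit 5",
    "ND6": "NADH dehydrogenase subunit 6",
    "COX1": "cytochrome c oxidase subunit I",
    "COX2": "cytochrome c oxidase subunit II",
    "COX3": "cytochrome c oxidase subunit III",
    "ATP6": "ATP synthase F0 subunit 6",
    "ATP8": "ATP synthase F0 subunit 8",
    "CYTB": "cytochrome b",
}

#: anticodon -> isoacceptor label for the duplicated Leu/Ser tRNAs.
#: trnL1 reads CUN (anticodon UAG), trnL2 reads UUR (UAA);
#: trnS1 reads AGN (GCU or UCU), trnS2 reads UCN (UGA).
_ISOACCEPTOR_BY_ANTICODON = {
    ("L", "TAG"): "trnL1", ("L", "UAG"): "trnL1",
    ("L", "TAA"): "trnL2", ("L", "UAA"): "trnL2",
    ("S", "GCT"): "trnS1", ("S", "GCU"): "trnS1",
    ("S", "TCT"): "trnS1", ("S", "UCU"): "trnS1",
    ("S", "TGA"): "trnS2", ("S", "UGA"): "trnS2",
}


def _norm(raw: str) -> str:
    return re.sub(r"[^a-z0-9]", "", raw.lower())


def _build_alias_table() -> dict[str, str]:
    t: dict[str, str] = {}

    def add(alias: str, label: str) -> None:
        t[_norm(alias)] = label

    roman = {"1": "i", "2": "ii", "3": "iii"}
    for lab in PCGS:
        add(lab, lab)
        add(_PCG_PRODUCTS[lab], lab)
    for i in "123456":
        add(f"nad{i}", f"ND{i}")
        add(f"nd{i}", f"ND{i}")
        add(f"nadh{i}", f"ND{i}")
    add("nad4l", "ND4L")
    add("ndl4", "ND4L")
    for i in "123":
        add(f"cox{i}", f"COX{i}")
        add(f"co{i}", f"COX{i}")
        add(f"co{roman[i]}", f"COX{i}")
        add(f"cox{roman[i]}", f"COX{i}")
    add("cob", "CYTB")
    add("cytb", "CYTB")
    add("cyb", "CYTB")
    add("cytochrome b", "CYTB")
    add("atp6", "ATP6")
    add("atp8", "ATP8")
    add("atpase6", "ATP6")
    add("atpase8", "ATP8")
    add("atpase subunit 6", "ATP6")
    add("atpase subunit 8", "ATP8")

    for lab in TRNAS:
        add(lab, lab)
        aa = lab[3]
        suffix = lab[4:]  # "", "1" or "2"
        add(f"trn{aa}{suffix}", lab)
        if not suffix:
            add(f"tRNA-{_AA3[aa]}", lab)
            add(f"trna{_AA3[aa]}", lab)
    # anticodon-tagged spellings, e.g. "trnL-uag", "tRNA-Ser(uga)"
    for (aa, anti), lab in _ISOACCEPTOR_BY_ANTICODON.items():
        add(f"trn{aa}{anti}", lab)
        add(f"tRNA-{_AA3[aa]}-{anti}", lab)
        add(f"tRNA-{_AA3[aa]}({anti})", lab)

    add("rrnS", "rrnS")
    add("rrnL", "rrnL")
    add("srrna", "rrnS")
    add("lrrna", "rrnL")
    add("s-rRNA", "rrnS")
    add("l-rRNA", "rrnL")
    add("12s", "rrnS")
    add("16s", "rrnL")
    add("12s rrna", "rrnS")
    add("16s rrna", "rrnL")
    add("12s ribosomal rna", "rrnS")
    add("16s ribosomal rna", "rrnL")
    add("small subunit ribosomal rna", "rrnS")
    add("large subunit ribosomal rna", "rrnL")

    add("cr", CR)
    add("control region", CR)
    add("putative control region", CR)
    add("d-loop", CR)
    add("at-rich region", CR)
    add("a+t-rich region", CR)
    add("ncr", NCR)
    add("non-coding region", NCR)
    add("noncoding region", NCR)
    return t


_ALIAS = _build_alias_table()


def canonical_gene_name(raw: str, anticodon: str | None = None) -> str:
    """Map a raw gene/product name onto the controlled vocabulary.

    Case- and punctuation-insensitive.  Plain ``tRNA-Leu``/``tRNA-Ser``
    need an anticodon to pick the isoacceptor; without one they fall
    through as flagged.  Unknown names are returned as
    ``unknown:<raw>`` rather than raising -- real records are messy and
    a single odd feature must not abort a run.
    """
    key = _norm(raw)
    if anticodon and key in (_norm("tRNA-Leu"), "trnl", _norm("tRNA-Ser"), "trns"):
        aa = "L" if "l" in key[-3:] or "leu" in key else "S"
        lab = _ISOACCEPTOR_BY_ANTICODON.get((aa, anticodon.upper().replace("U", "T")))
        if lab:
            return lab
    hit = _ALIAS.get(key)
    if hit is not None:
        if hit in ("trnL", "trnS"):  # ambiguous isoacceptor, no anticodon
            return UNKNOWN_PREFIX + raw
        return hit
    return UNKNOWN_PREFIX + raw


# ambiguous bare Leu/Ser names must stay flagged
_ALIAS.pop(_norm("tRNA-Leu"), None)
_ALIAS.pop(_norm("tRNA-Ser"), None)
_ALIAS.pop("trnl", None)
_ALIAS.pop("trns", None)


# ---------------------------------------------------------------------------
# GenBank I/O

_GB_TYPE_BY_CAT = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                   "CR": "misc_feature", "NCR": "misc_feature"}


def _location_for(f: GeneFeature, length: int) -> SimpleLocation | CompoundLocation:
    strand = +1 if f.strand == J else -1
    if f.end <= length:
        return SimpleLocation(f.start, f.end, strand=strand)
    head = SimpleLocation(f.start, length, strand=strand)
    tail = SimpleLocation(0, f.end - length, strand=strand)
    return CompoundLocation([head, tail])


def _span_from_location(loc, length: int) -> tuple[int, int]:
    parts = sorted(loc.parts, key=lambda p: int(p.start))
    if len(parts) == 1:
        return int(parts[0].start), int(parts[0].end)
    if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == length:
        # join across the origin -> wrap convention
        return int(parts[1].start), length + int(parts[0].end)
    raise ValueError(f"unsupported compound location {loc}")


def write_genbank(genomes: Iterable[Mitogenome], path: str | Path) -> None:
    """Write records as GenBank flat files (one file, possibly multi-record)."""
    records = []
    for g in genomes:
        rec = SeqRecord(
            Seq(g.sequence),
            id=g.accession,
            name=re.sub(r"\W", "", g.accession)[:16] or "MITO",
            description=f"{g.organism} mitochondrion, complete genome",
            annotations={
                "molecule_type": "DNA",
                "topology": g.topology,
                "organism": g.organism,
                "source": f"mitochondrion {g.organism}",
            },
        )
        for f in g.features:
            quals: dict[str, list[str]] = {"gene": [f.label]}
            if f.category == "PCG":
                quals["product"] = [_PCG_PRODUCTS.get(f.label, f.label)]
            elif f.category == "tRNA":
                aa3 = _AA3.get(f.label[3] if len(f.label) > 3 else "", "Xaa")
                quals["product"] = [f"tRNA-{aa3}"]
            elif f.category == "rRNA":
                quals["product"] = ["12S ribosomal RNA" if f.label == "rrnS"
                                    else "16S ribosomal RNA"]
            elif f.category == "CR":
                quals["note"] = ["putative control region (A+T-rich region)"]
            elif f.category == "NCR":
                quals["note"] = ["non-coding region"]
            rec.features.append(SeqFeature(
                _location_for(f, len(g)), type=_GB_TYPE_BY_CAT.get(f.category, "misc_feature"),
                qualifiers=quals))
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


def _feature_from_seqfeature(sf: SeqFeature, length: int) -> GeneFeature | None:
    if sf.type not in ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop"):
        return None
    quals = sf.qualifiers
    anticodon = None
    if "anticodon" in quals:
        m = re.search(r"seq:([a-zA-Z]{3})", quals["anticodon"][0])
        anticodon = m.group(1) if m else quals["anticodon"][0][-3:]
    raw = None
    for key in ("gene", "product", "note"):
        if key in quals and quals[key]:
            raw = quals[key][0]
            label = canonical_gene_name(raw, anticodon=anticodon)
            if not label.startswith(UNKNOWN_PREFIX):
                break
    if raw is None:
        if sf.type == "D-loop":
            label = CR
        else:
            return None
    if sf.type == "D-loop":
        label = CR
    start, end = _span_from_location(sf.location, length)
    strand = N if (sf.location.strand or 1) < 0 else J
    cat = category_of(label)
    if cat == "unknown":
        cat = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}.get(sf.type, "NCR")
    return GeneFeature(label=label, category=cat, strand=strand,
                       start=start, end=end)


def read_genbank(path: str | Path) -> list[Mitogenome]:
    """Parse a GenBank flat file into :class:`Mitogenome` objects.

    Feature names are canonicalized; unmappable names are carried as
    flagged ``unknown:<raw>`` features with a warning.  Coordinates are
    converted from the 1-based inclusive flat-file convention to 0-based
    half-open, with origin-spanning ``join()`` locations collapsed to
    the wrap convention (``end > length``).
    """
    genomes: list[Mitogenome] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        length = len(rec.seq)
        feats: list[GeneFeature] = []
        warns: list[str] = []
        ncr_count = 0
        for sf in rec.features:
            if sf.type == "source":
                continue
            gf = _feature_from_seqfeature(sf, length)
            if gf is None:
                continue
            if gf.label == NCR:
                ncr_count += 1
                if ncr_count > 1:
                    gf = replace(gf, label=f"NCR_{ncr_count}")
            if gf.flagged:
                warns.append(f"unmappable feature name: {gf.label[len(UNKNOWN_PREFIX):]!r}")
                warnings.warn(warns[-1])
            feats.append(gf)
        genomes.append(Mitogenome(
            accession=rec.id,
            organism=rec.annotations.get("organism", rec.description.split(" mitochondrion")[0]),
            topology=rec.annotations.get("topology", "linear"),
            sequence=str(rec.seq).upper(),
            features=feats,
            warnings=warns,
        ))
    if not genomes:
        raise ValueError(f"no GenBank records parsed from {path}")
    return genomes


def read_fasta(path: str | Path) -> list[Mitogenome]:
    """Sequence-only read; returns records with empty feature lists."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(Mitogenome(accession=rec.id, organism=rec.description,
                              topology="circular", sequence=str(rec.seq).upper()))
    if not out:
        raise ValueError(f"no FASTA records parsed from {path}")
    return out


# ---------------------------------------------------------------------------
# sequence extraction and feature tables

def extract_gene_sequence(g: Mitogenome, f: GeneFeature) -> str:
    """Gene sequence in reading orientation (reverse complement on N).

    Origin-spanning features concatenate the genome tail and head.
    """
    L = len(g)
    if not (0 <= f.start < L) or f.length > L:
        raise ValueError(f"{f.label}: coordinates outside modular range")
    if f.end <= L:
        s = g.sequence[f.start:f.end]
    else:
        s = g.sequence[f.start:] + g.sequence[: f.end - L]
    return revcomp(s) if f.strand == N else s


_TABLE_COLUMNS = ("label", "category", "strand", "start", "end", "length")


def write_feature_table(g: Mitogenome, path: str | Path | None = None) -> str:
    """Feature table as TSV, 1-based inclusive coordinates, ordered by start."""
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(_TABLE_COLUMNS)
    for f in sorted(g.features, key=lambda f: (f.start, f.end)):
        w.writerow([f.label, f.category, f.strand, f.start + 1, f.end, f.length])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_feature_table(text_or_path: str | Path) -> list[GeneFeature]:
    """Inverse of :func:`write_feature_table` (accepts text or a path)."""
    p = Path(str(text_or_path))
    text = p.read_text() if "\n" not in str(text_or_path) and p.exists() else str(text_or_path)
    rows = list(csv.reader(io.StringIO(text), delimiter="\t"))
    if not rows or tuple(rows[0]) != _TABLE_COLUMNS:
        raise ValueError("not a feature table")
    feats = []
    for label, category, strand, start, end, _length in rows[1:]:
        feats.append(GeneFeature(label=label, category=category, strand=strand,
                                 start=int(start) - 1, end=int(end)))
    return feats
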