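"""Comparative analysis over a set of annotated mitogenomes.

``run_comparative`` reads every input genome, computes the per-genome
summary (length, AT%, skews, gene counts, control-region length and
AT%), the per-PCG start/stop table, codon usage with RSCU, the
spacer/overlap table with motif hits, control-region tandem repeats, and
the gene-order rearrangement report against a reference order (the
ancestral insect arrangement by default), with single-TDRL scenarios
attached when the rearrangement admits them.

Outputs are plain TSV/JSON and are byte-stable for fixed inputs and
configuration.  Whole-genome percentages are printed at one decimal
place and control-region percentages at two, the precisions customary in
mitogenome description papers; full-precision values go to the JSON twin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .codon_usage import (
    count_codons, family_of, identify_start_codon, identify_stop_codon, rscu,
)
from .composition import region_composition
from .gene_order import (
    ANCESTRAL_GENE_ORDER, GeneOrder, classify_rearrangement, extract_gene_order,
)
from .genes import J, N, PCGS
from .mito_io import Mitogenome, extract_gene_sequence, read_genbank
from .region_scan import adjacent_spacers, exact_tandem_repeats, homopolymer_runs, locate_control_region

__all__ = ["RunConfig", "run_comparative"]

DEFAULT_MOTIFS = ("TACTAA", "TACTA")


@dataclass
class RunConfig:
    inputs: list[str]
    outdir: str = "scarabmito_out"
    reference_order: GeneOrder = field(default_factory=lambda: ANCESTRAL_GENE_ORDER)
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    homopolymer_min_len: int = 6
    repeat_unit_range: tuple[int, int] = (2, 200)
    repeat_min_copies: float = 2.0
    start_window: int = 60
    igs_min_len: int = 1
    igs_summary_threshold: int = 5


def _fmt(x: float, nd: int) -> str:
    return "nan" if isinstance(x, float) and math.isnan(x) else f"{x:.{nd}f}"


def _reading_upstream(g: Mitogenome, pcg) -> "object":
    """The pcg's 5'-adjacent neighbour: the previous feature in genome
    order for J-strand genes, the next one for N-strand genes."""
    feats = sorted(g.features, key=lambda f: (f.start, f.end))
    i = feats.index(pcg)
    return feats[i - 1] if pcg.strand == J else feats[(i + 1) % len(feats)]


def analyze_genome(g: Mitogenome, cfg: RunConfig) -> dict:
    """All per-genome results as one dictionary of plain values."""
    whole = region_composition(g, "genome")
    res: dict = {
        "accession": g.accession,
        "organism": g.organism,
        "length": len(g),
        "at_percent": 100 * whole.at_fraction,
        "skew_at": whole.skew_at,
        "skew_gc": whole.skew_gc,
        "n_pcg": sum(f.category == "PCG" for f in g.features),
        "n_trna": sum(f.category == "tRNA" for f in g.features),
        "n_rrna": sum(f.category == "rRNA" for f in g.features),
    }
    for sel in ("PCG", "PCG:J", "PCG:N"):
        try:
            st = region_composition(g, sel)
            res[f"{sel}_at_percent"] = 100 * st.at_fraction
            res[f"{sel}_skew_at"] = st.skew_at
            res[f"{sel}_skew_gc"] = st.skew_gc
        except ValueError:
            pass

    cr = locate_control_region(g)
    res["cr_length"] = cr.length
    res["cr_at_percent"] = 100 * cr.at_fraction if not cr.zero_length else math.nan
    res["cr_bounded_by"] = cr.bounded_by[1]

    # start / stop calls
    calls = []
    pcg_feats = [f for f in g.features if f.category == "PCG" and f.label in PCGS]
    for f in pcg_feats:
        up = _reading_upstream(g, f)
        s = identify_start_codon(g, f, up, window=cfg.start_window)
        e = identify_stop_codon(g, f)
        calls.append({"gene": f.label,
                      "start_codon": s.start_codon, "start_class": s.start_class,
                      "start_offset": s.start_offset,
                      "stop_codon": e.stop_codon, "stop_class": e.stop_class,
                      "flags": sorted(set(s.flags + e.flags))})
    res["start_stop"] = calls

    # codon usage
    table = rscu(count_codons(extract_gene_sequence(g, f) for f in pcg_feats))
    res["total_codons"] = table.total_codons
    res["codon_table"] = {c: {"count": table.counts[c], "rscu": table.rscu[c],
                              "family": family_of(c)}
                          for c in sorted(table.counts)}

    # spacers, overlaps, motifs
    spacers = adjacent_spacers(g, motifs=cfg.motifs)
    res["spacers"] = [{"upstream": s.upstream, "downstream": s.downstream,
                       "length": s.length,
                       "motifs": [{"motif": m, "offset": o} for m, o in s.motif_hits]}
                      for s in spacers]
    res["n_overlaps"] = sum(1 for s in spacers if s.length < 0)
    res["n_igs"] = sum(1 for s in spacers if s.length >= cfg.igs_min_len)
    res["n_igs_at_threshold"] = sum(1 for s in spacers if s.length >= cfg.igs_summary_threshold)
    res["homopolymers"] = [
        {"upstream": s.upstream, "downstream": s.downstream,
         "base": b, "offset": off, "length": ln}
        for s in spacers if s.length > 0
        for b, off, ln in homopolymer_runs(s.sequence, cfg.homopolymer_min_len)]

    # control-region tandem repeats
    repeats = []
    if cr.feature is not None:
        lo, hi = cfg.repeat_unit_range
        cr_seq = extract_gene_sequence(g, cr.feature)
        hi = min(hi, len(cr_seq) // 2)
        repeats = exact_tandem_repeats(cr_seq, (lo, hi), cfg.repeat_min_copies)
    res["cr_repeats"] = [{"unit_length": r.unit_length, "copy_number": r.copy_number,
                          "start": r.start, "unit": r.unit_sequence}
                         for r in repeats]

    # rearrangement vs reference
    order = extract_gene_order(g)
    ncr_lengths = {f.label: f.length for f in g.features if f.category == "NCR"}
    report = classify_rearrangement(cfg.reference_order, order, ncr_lengths)
    res["gene_order"] = order.to_text()
    res["rearrangement"] = report.to_dict()
    return res


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_comparative(cfg: RunConfig) -> int:
    """Run the full analysis; returns a nonzero exit status iff any
    genome failed to parse (others are still processed)."""
    if not cfg.inputs:
        raise ValueError("no input genomes given")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: list[dict] = []
    failures: list[str] = []
    log: list[str] = [f"scarabmito {__version__}",
                      f"config: {cfg}"]
    for path in cfg.inputs:
        try:
            genomes = read_genbank(path)
        except Exception as exc:  # noqa: BLE001 - report and continue
            failures.append(f"{path}: {exc}")
            log.append(f"ERROR {path}: {exc}")
            continue
        for g in genomes:
            res = analyze_genome(g, cfg)
            results.append(res)
            for w in g.warnings:
                log.append(f"WARN {g.accession}: {w}")
    results.sort(key=lambda r: r["accession"])

    _write_tsv(outdir / "summary.tsv",
               ["accession", "organism", "length", "at_percent", "skew_at",
                "skew_gc", "n_pcg", "n_trna", "n_rrna", "cr_length",
                "cr_at_percent", "n_overlaps", "n_igs", "total_codons"],
               [[r["accession"], r["organism"], r["length"],
                 _fmt(r["at_percent"], 1), _fmt(r["skew_at"], 3),
                 _fmt(r["skew_gc"], 3), r["n_pcg"], r["n_trna"], r["n_rrna"],
                 r["cr_length"], _fmt(r["cr_at_percent"], 2),
                 r["n_overlaps"], r["n_igs"], r["total_codons"]]
                for r in results])

    _write_tsv(outdir / "start_stop.tsv",
               ["accession", "gene", "start_codon", "start_class",
                "start_offset", "stop_codon", "stop_class", "flags"],
               [[r["accession"], c["gene"], c["start_codon"], c["start_class"],
                 c["start_offset"], c["stop_codon"], c["stop_class"],
                 ";".join(c["flags"])]
                for r in results for c in r["start_stop"]])

    _write_tsv(outdir / "codon_rscu.tsv",
               ["accession", "codon", "family", "count", "rscu"],
               [[r["accession"], codon, d["family"], d["count"],
                 _fmt(d["rscu"], 3)]
                for r in results for codon, d in r["codon_table"].items()])

    _write_tsv(outdir / "spacers.tsv",
               ["accession", "upstream", "downstream", "length", "motifs"],
               [[r["accession"], s["upstream"], s["downstream"], s["length"],
                 ";".join(f"{m['motif']}@{m['offset']}" for m in s["motifs"])]
                for r in results for s in r["spacers"]])

    _write_tsv(outdir / "repeats.tsv",
               ["accession", "unit_length", "copy_number", "start", "unit"],
               [[r["accession"], t["unit_length"], _fmt(t["copy_number"], 2),
                 t["start"], t["unit"]]
                for r in results for t in r["cr_repeats"]])

    with open(outdir / "rearrangements.json", "w") as fh:
        json.dump({r["accession"]: dict(r["rearrangement"],
                                        gene_order=r["gene_order"])
                   for r in results}, fh, indent=2, sort_keys=True)

    with open(outdir / "full_results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=str)

    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return 1 if failures else 0
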