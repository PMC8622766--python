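"""Codon counting, RSCU normalization, amino-acid splits, and the
minimize-intergenic-space start/stop calling rules."""

import numpy as np
import pytest

from scarabmito.codon_usage import (
    FAMILIES, CodonUsageTable, amino_acid_composition, count_codons,
    identify_start_codon, identify_stop_codon, rscu, start_candidate_rank,
)
from scarabmito.genes import revcomp
from scarabmito.mito_io import GeneFeature, Mitogenome


def test_count_codons_excludes_terminal_stop_and_remainder():
    t = count_codons(["ATGTTTTAA"])
    assert t.total_codons == 2
    assert t.counts["ATG"] == 1 and t.counts["TTT"] == 1
    assert count_codons(["ATGT"]).total_codons == 1  # incomplete stop T dropped


def test_count_codons_additive():
    one = count_codons(["ATGTTTTAA"])
    two = count_codons(["ATGTTTTAA", "ATGTTTTAA"])
    assert {c: 2 * n for c, n in one.counts.items()} == two.counts


def test_count_codons_skips_ambiguous():
    t = count_codons(["ATGNNNTTT"])
    assert t.total_codons == 2 and t.ambiguous_skipped == 1


def test_table5_family_structure():
    # invertebrate mitochondrial code: ATA is Met, TGA is Trp, AGA/AGG are Ser
    assert set(FAMILIES["Met"]) == {"ATA", "ATG"}
    assert set(FAMILIES["Trp"]) == {"TGA", "TGG"}
    assert set(FAMILIES["Ser1"]) == {"AGA", "AGG", "AGC", "AGT"}
    assert set(FAMILIES["Ser2"]) == {"TCA", "TCC", "TCG", "TCT"}
    assert set(FAMILIES["Leu1"]) == {"CTA", "CTC", "CTG", "CTT"}
    assert set(FAMILIES["Leu2"]) == {"TTA", "TTG"}
    assert sum(len(v) for v in FAMILIES.values()) == 62  # all sense codons


@pytest.mark.parametrize("counts,expected", [
    ({"AAA": 10, "AAG": 10}, {"AAA": 1.0, "AAG": 1.0}),
    ({"AAA": 20, "AAG": 0}, {"AAA": 2.0, "AAG": 0.0}),
    ({"GGA": 4, "GGC": 2, "GGG": 1, "GGT": 1}, {"GGA": 2.0, "GGC": 1.0,
                                                "GGG": 0.5, "GGT": 0.5}),
])
def test_rscu_values(counts, expected):
    t = CodonUsageTable()
    t.counts.update(counts)
    rscu(t)
    for codon, want in expected.items():
        assert t.rscu[codon] == pytest.approx(want)


def test_rscu_family_mean_is_one():
    rng = np.random.default_rng(5)
    t = CodonUsageTable()
    for c in t.counts:
        t.counts[c] = int(rng.integers(0, 50))
    rscu(t)
    for fam, codons in FAMILIES.items():
        if sum(t.counts[c] for c in codons):
            assert np.mean([t.rscu[c] for c in codons]) == pytest.approx(1.0)


def test_amino_acid_composition_split_and_zero():
    t = CodonUsageTable()
    t.counts["AAA"] = 20  # Lys
    t.counts["TTA"] = 3   # Leu2
    t.counts["CTT"] = 2   # Leu1
    aa = amino_acid_composition(t)
    assert aa["Lys"] == 20 and aa["Leu2"] == 3 and aa["Leu1"] == 2
    empty = amino_acid_composition(CodonUsageTable())
    assert set(empty.values()) == {0}


def test_codon_conservation(cet):
    """Total codon count x3 never exceeds the summed CDS lengths."""
    from scarabmito.mito_io import extract_gene_sequence
    genome, _ = cet
    pcgs = [f for f in genome.features if f.category == "PCG"]
    seqs = [extract_gene_sequence(genome, f) for f in pcgs]
    t = count_codons(seqs)
    assert 3 * t.total_codons <= sum(len(s) for s in seqs)
    # equality after removing the 13 stops (complete or incomplete)
    assert 3 * t.total_codons == sum(3 * (len(s) // 3) for s in seqs) - \
        3 * sum(1 for s in seqs if len(s) % 3 == 0)


# ---------------------------------------------------------------------------
# start / stop identification

def _genome_with_pcg(gene_body: str, upstream_len: int = 65, gap: str = ""):
    """Upstream tRNA, optional gap bases, then a J-strand PCG."""
    seq = "ACGT" * (upstream_len // 4 + 1)
    up_seq = seq[:upstream_len]
    full = up_seq + gap + gene_body + "CCGG"
    up = GeneFeature("trnT", "tRNA", "J", 0, upstream_len)
    start = upstream_len + len(gap)
    pcg = GeneFeature("COX1", "PCG", "J", start, start + len(gene_body))
    return Mitogenome(accession="S", organism="s", topology="circular",
                      sequence=full, features=[up, pcg]), pcg, up


def test_atypical_start_nearer_than_canonical_wins():
    """AAC one base after the upstream tRNA beats a canonical ATN 34 bp
    downstream -- the geometry that makes AAC the accepted COX1 start."""
    # codon index 11 (offset 34) is the nearest canonical ATN; all body
    # codons in between are non-candidates (CCT)
    body = "AAC" + "CCT" * 10 + "ATA" + "CCT" * 5 + "T"
    g, pcg, up = _genome_with_pcg(body, gap="G")
    call = identify_start_codon(g, pcg, up)
    assert call.start_codon == "AAC"
    assert call.start_class == "atypical-AAN"
    assert call.start_offset == 1


def test_canonical_preferred_on_offset_tie():
    assert start_candidate_rank("ATA", 0) < start_candidate_rank("AAT", 0)
    assert start_candidate_rank("AAT", 0) < start_candidate_rank("GTC", 0)
    # but a nearer atypical candidate beats a farther canonical one
    assert start_candidate_rank("AAC", 1) < start_candidate_rank("ATG", 34)


def test_no_candidate_within_window_is_no_call():
    body = "CCT" * 30 + "TAA"
    g, pcg, up = _genome_with_pcg(body)
    call = identify_start_codon(g, pcg, up, window=60)
    assert call.no_call


def test_stop_codon_calls():
    # complete TAG
    g, pcg, up = _genome_with_pcg("ATG" + "CCT" * 5 + "TAG")
    assert identify_stop_codon(g, pcg).stop_codon == "TAG"
    assert identify_stop_codon(g, pcg).stop_class == "complete"
    # incomplete T
    g, pcg, up = _genome_with_pcg("ATG" + "CCT" * 5 + "T")
    call = identify_stop_codon(g, pcg)
    assert (call.stop_codon, call.stop_class) == ("T", "incomplete")
    # incomplete TA, flagged distinctly
    g, pcg, up = _genome_with_pcg("ATG" + "CCT" * 5 + "TA")
    call = identify_stop_codon(g, pcg)
    assert (call.stop_codon, call.stop_class) == ("TA", "incomplete")
    assert "incomplete-TA" in call.flags


def test_premature_stop_flagged():
    body = "ATG" + "CCT" * 4 + "TAA" + "CCT" * 94 + "TAA"
    g, pcg, up = _genome_with_pcg(body)
    call = identify_stop_codon(g, pcg)
    assert "premature-stop" in call.flags


def test_start_stop_recovered_on_n_strand():
    """An N-strand PCG reads right-to-left; its upstream neighbour sits at
    higher genome coordinates."""
    reading = "ATG" + "CCT" * 5 + "TAA"
    genome_seq = "AAAA" + revcomp(reading) + "CCCC" + "ACGT" * 16
    pcg = GeneFeature("ND1", "PCG", "N", 4, 4 + len(reading))
    up = GeneFeature("trnL1", "tRNA", "N", 4 + len(reading) + 4,
                     4 + len(reading) + 4 + 60)
    g = Mitogenome(accession="NS", organism="n", topology="circular",
                   sequence=genome_seq[:len("AAAA") + len(reading) + 4 + 60],
                   features=[pcg, up])
    call = identify_start_codon(g, pcg, up)
    assert call.start_codon == "ATG"
    assert call.start_offset == 4
    assert identify_stop_codon(g, pcg).stop_codon == "TAA"


def test_generator_start_stop_ground_truth(cet, dyn):
    """On synthetic genomes the calls recover the construction for all PCGs."""
    from scarabmito.pipeline import RunConfig, analyze_genome
    for genome, gt in (cet, dyn):
        res = analyze_genome(genome, RunConfig(inputs=[]))
        for call in res["start_stop"]:
            assert call["start_codon"] == gt.starts[call["gene"]]["codon"]
            assert call["start_offset"] == gt.starts[call["gene"]]["offset"]
            assert call["stop_codon"] == gt.stops[call["gene"]]
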