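"""Spacers/overlaps on the circle, IUPAC motif search, homopolymers,
exact tandem repeats, and control-region location."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scarabmito.mito_io import GeneFeature, Mitogenome
from scarabmito.region_scan import (
    adjacent_spacers, exact_tandem_repeats, find_motif, homopolymer_runs,
    locate_control_region,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


# ---------------------------------------------------------------------------
# spacers

def test_overlap_and_origin_spacer(tiny_genome):
    recs = adjacent_spacers(tiny_genome)
    by_pair = {(r.upstream, r.downstream): r for r in recs}
    assert by_pair[("trnA", "trnC")].length == 1
    assert by_pair[("trnC", "trnA")].length == -1  # wrap overlap


def test_trnw_trnc_overlap_recovered(cet, dyn):
    for genome, gt in (cet, dyn):
        recs = {(r.upstream, r.downstream): r.length
                for r in adjacent_spacers(genome)}
        assert recs[("trnW", "trnC")] == -8
        for sp in gt.spacers:
            assert recs[(sp["upstream"], sp["downstream"])] == sp["length"]


def test_origin_gap():
    g = Mitogenome(
        accession="G", organism="g", topology="circular", sequence="A" * 100,
        features=[GeneFeature("trnA", "tRNA", "J", 10, 40),
                  GeneFeature("trnC", "tRNA", "J", 40, 70)])
    recs = {(r.upstream, r.downstream): r for r in adjacent_spacers(g)}
    assert recs[("trnA", "trnC")].length == 0
    assert recs[("trnA", "trnC")].sequence == ""
    wrap = recs[("trnC", "trnA")]
    assert wrap.length == 40  # 30 to the origin + 10 past it
    assert len(wrap.sequence) == 40


def test_circular_conservation(cet, dyn, dyn_long_ncr):
    for genome, _ in (cet, dyn, dyn_long_ncr):
        spacers = adjacent_spacers(genome)
        total = sum(f.length for f in genome.features) + sum(s.length for s in spacers)
        assert total == len(genome)


def test_motif_hits_attached_to_spacers(cet, dyn):
    for (genome, gt), motif in ((cet, "TACTAA"), (dyn, "TACTA")):
        recs = {(r.upstream, r.downstream): r
                for r in adjacent_spacers(genome, motifs=(motif,))}
        planted = gt.motifs[0]
        rec = recs[(planted["upstream"], planted["downstream"])]
        assert (motif, planted["offset"]) in rec.motif_hits


# ---------------------------------------------------------------------------
# motifs

def test_find_motif_basics():
    assert find_motif("xxTACTAAxx".replace("x", "G"), "TACTAA") == [2]
    assert find_motif("GGGG", "TACTA") == []
    assert find_motif("TACTACTA", "TACTA") == [0, 3]  # overlapping hits


def test_find_motif_iupac():
    assert find_motif("AACAAT", "AAN") == [0, 3]
    assert find_motif("ATGATA", "ATR") == [0, 3]  # R = A or G
    assert find_motif("ACTATT", "ATY") == [3]  # Y = C or T
    with pytest.raises(ValueError):
        find_motif("ACGT", "AXC")


@given(dna, st.sampled_from(["TACTA", "AT", "GGC"]))
@settings(deadline=None)
def test_find_motif_matches_naive_scan(seq, motif):
    naive = [i for i in range(len(seq) - len(motif) + 1)
             if seq[i:i + len(motif)] == motif]
    assert find_motif(seq, motif) == naive


# ---------------------------------------------------------------------------
# homopolymers

def test_homopolymer_runs():
    assert homopolymer_runs("AACCCCCCCCCCCA", 11) == [("C", 2, 11)]
    assert homopolymer_runs("ACGT", 2) == []
    assert homopolymer_runs("ACGTTTT", 4) == [("T", 3, 4)]  # run at the end


def test_c_stretch_recovered(dyn):
    genome, gt = dyn
    planted = gt.homopolymers[0]
    runs = homopolymer_runs(genome.sequence[planted["position"] - 2:
                                            planted["position"] + planted["length"] + 2],
                            min_len=planted["length"])
    assert runs == [(planted["base"], 2, planted["length"])]


# ---------------------------------------------------------------------------
# tandem repeats

def naive_tandem_repeats(seq, unit_range, min_copies):
    """Oracle: check every (start, unit) pair directly."""
    out = []
    n = len(seq)
    lo, hi = max(unit_range[0], 1), min(unit_range[1], n // 2)
    for u in range(lo, hi + 1):
        for p in range(n - 2 * u + 1):
            if seq[p:p + u] != seq[p + u:p + 2 * u]:
                continue
            ext = 2 * u
            while p + ext < n and seq[p + ext] == seq[p + ext - u]:
                ext += 1
            unit = seq[p:p + u]
            smallest = next((q for q in range(1, u) if u % q == 0
                             and unit == unit[:q] * (u // q)), u)
            if (ext / u >= min_copies and smallest == u
                    and (p == 0 or seq[p - 1] != seq[p + u - 1])):
                out.append((u, ext / u, p, unit))
    return sorted(out)


def test_exact_tandem_repeats_basics():
    recs = exact_tandem_repeats("ATGATGATG", (2, 5), 2)
    assert [(r.unit_sequence, r.copy_number, r.start) for r in recs] == [("ATG", 3.0, 0)]
    # smallest-period rule: AAAA has period 1, below the unit range
    assert exact_tandem_repeats("AAAA", (2, 2), 2) == []


def test_repeats_validate_and_match_oracle():
    rng = np.random.default_rng(3)
    for _ in range(30):
        n = int(rng.integers(20, 120))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        got = exact_tandem_repeats(seq, (2, 10), 2)
        assert sorted((r.unit_length, r.copy_number, r.start, r.unit_sequence)
                      for r in got) == naive_tandem_repeats(seq, (2, 10), 2)
        for r in got:
            assert r.validates_on(seq)


def test_planted_cr_repeat_recovered(cet):
    genome, gt = cet
    planted = gt.cr_repeat
    cr = gt.cr
    cr_seq = genome.sequence[cr["start"]:cr["end"]]
    u = planted["unit_length"]
    recs = exact_tandem_repeats(cr_seq, (u, u), 2)
    hits = [r for r in recs
            if r.unit_sequence == planted["unit_sequence"]
            and r.start + cr["start"] == planted["start"]
            and r.copy_number == planted["copies"]]
    assert hits


# ---------------------------------------------------------------------------
# control region

def test_locate_cr_templates(cet, dyn):
    for (genome, gt), bound in ((cet, "trnI"), (dyn, "trnQ")):
        cr = locate_control_region(genome)
        assert cr.bounded_by == ("rrnS", bound)
        assert cr.length == gt.cr["length"]
        assert cr.feature.start == gt.cr["start"] % len(genome)
        assert cr.at_fraction > 0.7


def test_locate_cr_zero_length_flag():
    g = Mitogenome(
        accession="Z", organism="z", topology="circular", sequence="A" * 60,
        features=[GeneFeature("rrnS", "rRNA", "N", 0, 30),
                  GeneFeature("trnI", "tRNA", "J", 30, 60)])
    cr = locate_control_region(g)
    assert cr.zero_length and cr.length == 0


def test_locate_cr_requires_rrns():
    g = Mitogenome(
        accession="Z", organism="z", topology="circular", sequence="A" * 60,
        features=[GeneFeature("trnI", "tRNA", "J", 30, 60)])
    with pytest.raises(ValueError):
        locate_control_region(g)
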