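"""Circular gene orders: rotation handling, breakpoint distance, moved
genes, rearrangement classification and single-TDRL enumeration."""

import itertools

import numpy as np
import pytest

from scarabmito.gene_order import (
    ANCESTRAL_GENE_ORDER, REARRANGED_GENE_ORDER, GeneOrder, apply_tdrl,
    breakpoint_distance, classify_ncr, classify_rearrangement,
    enumerate_single_tdrl, extract_gene_order, moved_genes, normalize_rotation,
)
from scarabmito.genes import ANCESTRAL_ORDER
from scarabmito.mito_io import GeneFeature, Mitogenome


def O(text):  # noqa: E743 - terse order builder
    return GeneOrder.from_text(text)


def tdrl_reachable_oracle(source):
    """Independent brute force: all orders reachable by one tandem
    duplication + random loss, built by partitioning each block into the
    genes kept in the first vs the second copy."""
    src = tuple(source)
    out = set()
    n = len(src)
    for i in range(n):
        for j in range(i, n):
            block = src[i:j + 1]
            for mask in range(2 ** len(block)):
                first = tuple(e for k, e in enumerate(block) if mask >> k & 1)
                second = tuple(e for k, e in enumerate(block) if not mask >> k & 1)
                out.add(src[:i] + first + second + src[j + 1:])
    return out


def test_ancestral_order_strand_partition():
    """9 PCGs + 14 tRNAs on J; 4 PCGs, 8 tRNAs, both rRNAs on N."""
    from scarabmito.genes import PCGS, RRNAS, TRNAS
    plus = {lab for lab, s in ANCESTRAL_ORDER if s > 0}
    minus = {lab for lab, s in ANCESTRAL_ORDER if s < 0}
    assert len([g for g in plus if g in PCGS]) == 9
    assert len([g for g in plus if g in TRNAS]) == 14
    assert len([g for g in minus if g in PCGS]) == 4
    assert len([g for g in minus if g in TRNAS]) == 8
    assert set(RRNAS) <= minus


def test_extract_order_round_trip(cet, dyn):
    g, _ = cet
    assert extract_gene_order(g) == ANCESTRAL_GENE_ORDER
    d, _ = dyn
    od = extract_gene_order(d)
    assert od == REARRANGED_GENE_ORDER
    labs = od.labels
    i = labs.index("CR")
    run = [labs[(i + k) % len(labs)] for k in range(5)]
    assert run == ["CR", "trnQ", "NCR", "trnI", "trnM"]


def test_extract_order_duplicate_label_errors():
    g = Mitogenome(
        accession="D", organism="d", topology="circular", sequence="ACGTACGTACGT",
        features=[GeneFeature("trnI", "tRNA", "J", 0, 3),
                  GeneFeature("trnI", "tRNA", "J", 4, 7)])
    with pytest.raises(ValueError, match="duplicate"):
        extract_gene_order(g)


def test_normalize_rotation():
    o = ANCESTRAL_GENE_ORDER
    n1 = normalize_rotation(o, "CR")
    assert n1.labels[0] == "CR" and n1.labels[1] == "trnI"
    assert normalize_rotation(n1, "CR") == n1  # idempotent
    assert n1.elements == normalize_rotation(
        GeneOrder(o.elements[5:] + o.elements[:5]), "CR").elements
    with pytest.raises(ValueError):
        normalize_rotation(o, "nope")


def test_breakpoint_distance_basics():
    a = O("CR,trnI,trnQ,trnM,ND2")
    assert breakpoint_distance(a, a) == 0
    rot = GeneOrder(a.elements[2:] + a.elements[:2])
    assert breakpoint_distance(a, rot) == 0
    b = O("CR,trnQ,trnI,trnM,ND2")
    # lost: {CR,trnI} and {trnQ,trnM}; {trnI,trnQ} survives unsigned
    assert breakpoint_distance(a, b) == 2
    assert breakpoint_distance(b, a) == 2  # symmetric
    with pytest.raises(ValueError):
        breakpoint_distance(a, O("CR,trnI,trnQ,trnM,ND3"))


def test_breakpoint_distance_ignores_ncr():
    assert breakpoint_distance(ANCESTRAL_GENE_ORDER, REARRANGED_GENE_ORDER) == 2


def test_moved_genes_identity_and_swap():
    a = O("A,B,C,D")
    assert moved_genes(a, a) == [frozenset()]
    optima = moved_genes(ANCESTRAL_GENE_ORDER, REARRANGED_GENE_ORDER)
    assert set(optima) == {frozenset({"trnI"}), frozenset({"trnQ"})}


def test_moved_genes_full_reversal_needs_two():
    a = O("A,B,C,D")
    b = O("D,C,B,A")
    optima = moved_genes(a, b)
    assert all(len(s) == 2 for s in optima)
    # exhaustive check: no singleton removal makes them rotation-equal
    for lab in "ABCD":
        ra = [e for e in a.elements if e[0] != lab]
        rb = [e for e in b.elements if e[0] != lab]
        assert GeneOrder(tuple(ra)) != GeneOrder(tuple(rb))


def test_classify_none_translocation_inversion():
    rep = classify_rearrangement(ANCESTRAL_GENE_ORDER, ANCESTRAL_GENE_ORDER)
    assert rep.event_class == "none" and rep.breakpoint_count == 0

    rep = classify_rearrangement(ANCESTRAL_GENE_ORDER, REARRANGED_GENE_ORDER,
                                 ncr_lengths={"NCR": 56})
    assert rep.event_class == "translocation"
    assert rep.tdrl_compatible
    assert rep.moved_genes <= {"trnI", "trnQ"}
    assert rep.ncrs and rep.ncrs[0][1:] == (56, "NCR1")

    flipped = tuple((lab, -s if lab == "trnI" else s)
                    for lab, s in ANCESTRAL_ORDER)
    rep = classify_rearrangement(ANCESTRAL_GENE_ORDER, GeneOrder(flipped))
    assert rep.event_class == "inversion"
    assert rep.moved_genes == {"trnI"}


def test_classify_ncr_thresholds():
    assert classify_ncr(56) == "NCR1"
    assert classify_ncr(99) == "NCR1"
    assert classify_ncr(412) == "NCR2"
    assert classify_ncr(250) == "intermediate"
    assert classify_ncr(100) == "intermediate"
    assert classify_ncr(400) == "intermediate"
    with pytest.raises(ValueError):
        classify_ncr(0)


def test_tdrl_swap_scenario_exists_with_cr_remnant():
    """Duplicating CR-trnI-trnQ-trnM and losing one copy of each gene can
    yield CR-trnQ-(NCR)-trnI-trnM, with the decayed CR copy among the
    remnant candidates at the NCR slot."""
    src = O("CR,trnI,-trnQ,trnM")
    tgt = O("CR,-trnQ,NCR,trnI,trnM")
    scenarios = enumerate_single_tdrl(src.elements, tgt.elements)
    assert scenarios
    for s in scenarios:
        assert s.reapply() == s.result  # executable re-application
    full = [s for s in scenarios if s.block == (0, 3)]
    assert full, "whole-cluster duplication must be among the scenarios"
    (ncr_idx, cands), = full[0].remnant_slots
    assert ("CR", 2) in cands or ("CR", 1) in cands


def test_tdrl_identity_always_reachable():
    src = O("trnI,trnQ,trnM")
    assert enumerate_single_tdrl(src.elements, src.elements)


def test_tdrl_full_reversal_unreachable():
    src = O("trnI,trnQ,trnM")
    tgt = O("trnM,trnQ,trnI")
    assert enumerate_single_tdrl(src.elements, tgt.elements) == []


def test_tdrl_never_changes_strand():
    src = O("trnI,-trnQ,trnM")
    tgt = O("trnI,trnQ,trnM")  # trnQ flipped
    assert enumerate_single_tdrl(src.elements, tgt.elements) == []


def test_tdrl_matches_bruteforce_oracle_small_windows():
    """Exhaustive agreement with the independent partition-based oracle on
    every permutation of up to 5 elements."""
    for n in (2, 3, 4, 5):
        labels = [f"g{k}" for k in range(n)]
        src = tuple((lab, 1) for lab in labels)
        reachable = tdrl_reachable_oracle(src)
        for perm in itertools.permutations(src):
            got = bool(enumerate_single_tdrl(src, perm))
            assert got == (perm in reachable), perm


def test_tdrl_scenarios_all_reproduce_target():
    rng = np.random.default_rng(42)
    for _ in range(50):
        n = int(rng.integers(2, 7))
        src = tuple((f"g{k}", 1) for k in range(n))
        perm = tuple(src[i] for i in rng.permutation(n))
        for s in enumerate_single_tdrl(src, perm):
            assert s.reapply() == perm


def test_order_text_round_trip():
    o = O("CR,-trnQ,NCR,trnI,trnM")
    assert GeneOrder.from_text(o.to_text()) == o
    assert o.to_text() == "CR,-trnQ,NCR,trnI,trnM"
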