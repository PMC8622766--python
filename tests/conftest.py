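"""Shared fixtures: synthetic genomes with ground truth, generated once."""

from __future__ import annotations

import pytest
from hypothesis import settings

from scarabmito.mito_io import GeneFeature, Mitogenome

settings.register_profile("deterministic", derandomize=True,
                          max_examples=50, deadline=None)
settings.load_profile("deterministic")
from scarabmito.synthetic_mitogenome import (
    cetoniinae_like, dynastinae_like, generate,
)


@pytest.fixture(scope="session")
def cet():
    """Ancestral-order genome (AAC COX1 start, TACTAA motif) + ground truth."""
    return generate(cetoniinae_like(seed=11))


@pytest.fixture(scope="session")
def dyn():
    """Rearranged trnQ-NCR-trnI-trnM genome (NCR 56 bp) + ground truth."""
    return generate(dynastinae_like(seed=12))


@pytest.fixture(scope="session")
def dyn_long_ncr():
    """Rearranged genome with the long 412 bp NCR variant."""
    return generate(dynastinae_like(seed=13, ncr_length=412))


@pytest.fixture()
def tiny_genome():
    """Six-base circular genome with hand-placed features, including one
    spanning the origin."""
    return Mitogenome(
        accession="TINY1", organism="test", topology="circular",
        sequence="ATGCCC",
        features=[
            GeneFeature(label="trnA", category="tRNA", strand="J", start=1, end=4),
            GeneFeature(label="trnC", category="tRNA", strand="J", start=5, end=8),
        ],
    )
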