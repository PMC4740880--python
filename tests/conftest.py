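"""Shared fixtures: a hand-built two-exon transcript and generated models."""

import numpy as np
import pytest

from riphewas.genome import Genome, TranscriptModel
from riphewas.simulate import random_marker_map, simulate_gene_models


@pytest.fixture(scope="session")
def mini_genome():
    """One '+' strand gene with fully known structure.

    Layout (0-based):
      0-5    intergenic CCCCC
      5-8    5' UTR TTT
      8-16   CDS part 1 ATGAAATA
      16-46  intron GT + A*26 + AG
      46-53  CDS part 2 TCCCTAA
      53-57  3' UTR GGGG
      57-80  intergenic C*23

    CDS reads ATG AAA TAT CCC TAA.
    """
    seq = (
        "CCCCC" + "TTT" + "ATGAAATA"
        + "GT" + "A" * 26 + "AG"
        + "TCCCTAA" + "GGGG" + "C" * 23
    )
    assert len(seq) == 80
    return Genome({"c": seq})


@pytest.fixture(scope="session")
def mini_transcript():
    return TranscriptModel(
        transcript_id="txA",
        gene_id="geneA",
        chromosome="c",
        strand="+",
        exons=((5, 16), (46, 57)),
        cds=((8, 16), (46, 53)),
    )


@pytest.fixture(scope="session")
def gene_models():
    """Ten generated genes (both strands) for oracle/property tests."""
    return simulate_gene_models(10, seed=101)


@pytest.fixture(scope="session")
def marker_map():
    return random_marker_map({"chr1": 40, "chr2": 20}, seed=7)
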