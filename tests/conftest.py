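import dendropy
import numpy as np
import pytest

from plastorate.seqio_align import CodonAlignment, GeneBlock


@pytest.fixture
def toy_alignment():
    """3 taxa, 2 genes (6 + 9 columns), gap-free."""
    seqs = {
        "A": "ATGAAA" + "TTTCCCGGG",
        "B": "ATGAAG" + "TTTCCAGGG",
        "C": "ATGAAA" + "TTCCCCGGA",
    }
    blocks = [GeneBlock("g1", 0, 6), GeneBlock("g2", 6, 15)]
    return CodonAlignment(taxa=["A", "B", "C"], sequences=seqs, gene_blocks=blocks)


@pytest.fixture
def gapped_alignment():
    seqs = {
        "A": "ATG---AAATTT",
        "B": "ATGCCCAAATTT",
        "C": "ATGCCCAAA---",
    }
    return CodonAlignment(taxa=["A", "B", "C"], sequences=seqs, gene_blocks=[GeneBlock("g1", 0, 12)])


@pytest.fixture
def three_taxon_tree():
    return dendropy.Tree.get(data="((A:1.0,B:1.0):1.0,C:2.0);", schema="newick")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
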