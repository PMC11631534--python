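import pytest

from mistrans.psm_pipeline import UniquePeptide
from mistrans.sequence_db import CodingGene, SequenceDatabase


@pytest.fixture
def toy_gene():
    """MKVTSK with codons ATG AAA GTT ACC TCT AAA and a TAA stop."""
    return CodingGene.from_sequences("gene1", "MKVTSK", "ATGAAAGTTACCTCTAAATAA")


@pytest.fixture
def toy_db(toy_gene):
    other = CodingGene.from_sequences("gene2", "MKAYWK", "ATGAAAGCTTACTGGAAATAA")
    return SequenceDatabase.from_genes([toy_gene, other])


def make_unique(seq, positions=(), sub_from="", sub_to="", psm_count=1, best_q=0.0):
    """Shorthand UniquePeptide constructor for fixtures."""
    return UniquePeptide(
        base_sequence=seq,
        sub_positions=tuple(positions),
        sub_from=sub_from,
        sub_to=sub_to,
        psm_count=psm_count,
        best_q=best_q,
    )
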