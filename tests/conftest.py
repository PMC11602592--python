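import numpy as np
import pandas as pd
import pytest

from spliceform.model import TranscriptModel
from spliceform.simulate import GeneratorConfig, generate


def make_tx(tid, exons, strand="+", gene="G1", chrom="chr1", category="unclassified"):
    return TranscriptModel(tid, gene, chrom, strand, exons, category=category)


@pytest.fixture(scope="session")
def small_dataset():
    """A fully generated 40-gene dataset shared across read-only tests."""
    return generate(GeneratorConfig(n_genes=40, seed=101))


@pytest.fixture()
def two_exon_tx():
    return make_tx("T1", [(100, 200), (300, 400)])


@pytest.fixture()
def toy_genome():
    # one contig with canonical dinucleotides at [3,5) GT and [10,12) AG
    return {"chr1": "AAAGTTTTTTAGCCC", "tiny": "AAATTTGGG"}
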