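import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from opxscreen.genome_io import GeneRecord, GeneTable, Thresholds


@pytest.fixture
def thresholds():
    return Thresholds()


def make_contig(n, genome="G0", contig="c1", spacing=100, protein_prefix="P"):
    """A linear contig of n coding genes with ranks 0..n-1."""
    genes = []
    for i in range(n):
        start = 1 + i * spacing
        genes.append(
            GeneRecord(
                gene_id=f"{genome}_g{i}",
                genome_id=genome,
                contig_id=contig,
                start=start,
                end=start + 50,
                strand="+" if i % 2 == 0 else "-",
                rank=i,
                protein_id=f"{protein_prefix}{i}",
            )
        )
    return GeneTable(genes)


@pytest.fixture
def contig12():
    return make_contig(12)
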