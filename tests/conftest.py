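import numpy as np
import pandas as pd
import pytest

from radgbs import simulate
from radgbs.model import GenotypeMatrix


@pytest.fixture(scope="session")
def small_genome():
    """A 60 kb single-chromosome genome with genes and repeats."""
    return simulate.generate_reference(
        60_000, n_chroms=1, gc_content=0.44, gene_density=2.0,
        repeat_density=0.05, seed=7,
    )


@pytest.fixture(scope="session")
def panel_truth(small_genome):
    """Structured 8-accession truth panel on the small genome."""
    genome, annotation = small_genome
    config = simulate.PanelConfig(seed=11, snp_density=20.0, indel_density=2.0)
    return simulate.generate_panel_variants(genome, annotation, config)


def make_matrix(codes, chrom="chr1", accessions=None):
    """Genotype matrix from a loci x accessions code array, with SNP
    loci at consecutive positions."""
    codes = np.asarray(codes, dtype=np.int8)
    n_loci, n_acc = codes.shape
    accessions = accessions or [f"A{i}" for i in range(n_acc)]
    loci = pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(n_loci) * 10,
        "ref": "A",
        "alt": "G",
        "vtype": "SNP",
    })
    return GenotypeMatrix(loci, accessions, codes)
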