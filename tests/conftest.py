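import numpy as np
import pytest

from scai import generate_paired_dataset, normalize_expression


@pytest.fixture(scope="session")
def small_discrete():
    """Small 3-cluster paired dataset with normalized expression."""
    data, truth = generate_paired_dataset(
        "discrete", n_cells=150, n_genes=200, n_loci=400, n_clusters=3,
        rna_sparsity=0.85, atac_sparsity=0.95, seed=7)
    X1 = normalize_expression(data.X1)
    return data, truth, X1


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_gtf(tmp_path):
    """Two-gene GTF: GeneA (+, TSS 1,000,000) and GeneB (-, TSS 2,000,000)."""
    path = tmp_path / "genes.gtf"
    path.write_text(
        'chr1\tsrc\tgene\t1000000\t1005000\t.\t+\t.\tgene_id "G1"; gene_name "GeneA";\n'
        'chr1\tsrc\tgene\t1995000\t2000000\t.\t-\t.\tgene_id "G2"; gene_name "GeneB";\n'
        'chr2\tsrc\tgene\t500000\t505000\t.\t+\t.\tgene_id "G3"; gene_name "GeneC";\n')
    return path
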