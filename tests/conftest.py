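import numpy as np
import pytest

from rtamod.reference import TRNAGene, cluster_identical
from rtamod.simulate import SimConfig, simulate_genes


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic gene set with its clusters (20 clusters, 60 genes)."""
    cfg = SimConfig(seed=11, n_clusters=20, total_genes=60, depth_mean=200)
    genes, clusters = simulate_genes(cfg)
    return cfg, genes, clusters


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_gene(seq, introns=(), gene_id="g1", anticodon=None, origin="nuclear",
              isotype="Ala", strand="+"):
    """Helper constructing a minimal valid TRNAGene around a raw sequence."""
    return TRNAGene(
        gene_id=gene_id,
        contig="chr1",
        start=1,
        end=len(seq),
        strand=strand,
        sequence=seq,
        anticodon=anticodon or "AGC",
        isotype=isotype,
        intron_intervals=tuple(introns),
        origin=origin,
    )
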