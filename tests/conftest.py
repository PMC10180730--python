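import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methprime.datasets import GeneAnnotation, MethylationDataset
from methprime.simulate import SimConfig, simulate_study

settings.register_profile("default", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("default")

SMALL = dict(
    chrom_length=4_000_000,
    n_genes=80,
    n_cpgs=4_000,
    n_planted_dmrs=40,
    n_ccres=150,
    n_planted_degs=10,
)


@pytest.fixture(scope="session")
def small_study():
    """A small planted-signal study reused across read-only tests."""
    return simulate_study(SimConfig(seed=5, **SMALL))


@pytest.fixture(scope="session")
def toy_annotation():
    """Three hand-placed genes on two chromosomes.

    gA: chr1 + strand, TSS 10_000;  gB: chr1 - strand, TSS 59_999;
    gC: chr2 + strand, TSS 5_000.
    """
    genes = pd.DataFrame(
        [
            ("gA", "chr1", 10_000, 15_000, "+"),
            ("gB", "chr1", 50_000, 60_000, "-"),
            ("gC", "chr2", 5_000, 9_000, "+"),
        ],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    return GeneAnnotation(genes=genes, chrom_sizes={"chr1": 1_000_000, "chr2": 100_000})


def make_methylation_dataset(rows, samples, groups):
    """Build a MethylationDataset from (chrom, pos, meth_row, unmeth_row) tuples."""
    sites = pd.DataFrame([(r[0], r[1]) for r in rows], columns=["chrom", "pos"])
    meth = np.array([r[2] for r in rows], dtype=np.int64)
    unmeth = np.array([r[3] for r in rows], dtype=np.int64)
    design = pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample"))
    return MethylationDataset(sites=sites, meth=meth, unmeth=unmeth,
                              samples=list(samples), design=design)
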