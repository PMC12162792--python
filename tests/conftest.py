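import numpy as np
import pandas as pd
import pytest

from promethyl.io_formats import AnnotationSet, CpGCountTable, PoolLabel, default_design
from promethyl.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=7, n_genes=120)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """One modest synthetic dataset shared across read-only tests."""
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def design(small_dataset):
    return default_design(small_dataset[1].pools)


@pytest.fixture
def two_pool_labels():
    return [
        PoolLabel("transgenic", "Day0", 1),
        PoolLabel("transgenic", "Day28", 1),
    ]


def make_cpg_table(meth, unmeth, pools, positions=None, chrom="chr1"):
    """Small helper: build a CpGCountTable from plain count lists."""
    meth = np.asarray(meth)
    if positions is None:
        positions = np.arange(meth.shape[0]) * 50 + 100
    sites = pd.DataFrame({"chrom": chrom, "pos": positions})
    return CpGCountTable(sites, meth, np.asarray(unmeth), pools)


def make_annotation(rows):
    return AnnotationSet(pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"]))
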