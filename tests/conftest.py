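import numpy as np
import pandas as pd
import pytest

from epimemo.genome import GeneModel, GenomicInterval, SampleSheet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_genes():
    """Three genes on two chromosomes, mixed strands."""
    return [
        GeneModel("gA", GenomicInterval("chr1", 6800, 9000), "+"),
        GeneModel("gB", GenomicInterval("chr1", 3000, 9000), "-"),
        GeneModel("gC", GenomicInterval("chr2", 100, 2100), "+"),
    ]


@pytest.fixture
def small_sheet():
    rows = []
    for group, tp, n in [("NC", "T1", 3), ("HFD", "T1", 3), ("NC-NC", "T2", 3), ("HFD-NC", "T2", 3)]:
        for r in range(1, n + 1):
            rows.append(
                dict(sample_id=f"ATAC_{group}_{r}", assay="ATAC", group=group,
                     timepoint=tp, replicate=r)
            )
    return SampleSheet(pd.DataFrame(rows))


def random_intervals(rng, n, genome, max_len=400):
    """Random valid intervals over a dict chrom->length."""
    chroms = list(genome)
    out = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, max(1, genome[c] - length)))
        out.append(GenomicInterval(c, start, start + length))
    return out
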