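import numpy as np
import pandas as pd
import pytest

from crelink.iofmt import GeneRecord, GenomicInterval
from crelink.matrixcore import OmicsPair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_pair():
    """10 cells, 3 peaks, 3 genes with hand-picked detection patterns."""
    cells = [f"c{i}" for i in range(10)]
    ca = pd.DataFrame(
        [
            [2, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # detected (>=2) in exactly 1/10 cells
            [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],  # never reaches 2 fragments
            [3, 3, 3, 3, 3, 3, 3, 3, 3, 3],  # everywhere
        ],
        index=["p0", "p1", "p2"],
        columns=cells,
    )
    ge = pd.DataFrame(
        [
            [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # expressed in 1/10 cells
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # never expressed
            [5, 5, 5, 5, 5, 5, 5, 5, 5, 5],
        ],
        index=["g0", "g1", "g2"],
        columns=cells,
    )
    peaks = [
        GenomicInterval("chr1", 100, 300),
        GenomicInterval("chr1", 1000, 1200),
        GenomicInterval("chr1", 5000, 5200),
    ]
    genes = [
        GeneRecord("g0", GenomicInterval("chr1", 200, 1200, "+")),
        GeneRecord("g1", GenomicInterval("chr1", 4000, 6000, "-")),
        GeneRecord("g2", GenomicInterval("chr2", 50, 900, "+")),
    ]
    return OmicsPair(ca=ca, ge=ge, peaks=peaks, genes=genes)
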