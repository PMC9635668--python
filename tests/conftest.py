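import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from mutspect import GenomeSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20220901)


@pytest.fixture
def toy_genome():
    """Two small chromosomes with hand-placed repeat and homology tracts."""
    return GenomeSequence(
        {
            "chr1": "AACGTACGTTAGCTAGGCATTTTACGATCGGCTAGCTAACCGGTT",
            "chr2": "TTGCAACGTGTGTGTGACCAAAAAGGCTTAGCTTAGGGCATCGA",
        }
    )


def random_genome(rng, n_chrom=2, length=300, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return GenomeSequence(
        {
            f"chr{i+1}": "".join(rng.choice(list("ACGT"), size=length, p=p))
            for i in range(n_chrom)
        }
    )
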