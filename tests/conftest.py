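import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import popdiff as pp

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


def make_snp_map(n, chrom="6", start=25_000_001, spacing=1000):
    return pp.SnpMap(pd.DataFrame({
        "snp_id": [f"snp{i+1}" for i in range(n)],
        "chrom": chrom,
        "pos": [start + i * spacing for i in range(n)],
        "allele0": "A",
        "allele1": "G",
    }))


@pytest.fixture
def snp_map3():
    return make_snp_map(3)


@pytest.fixture
def small_panel():
    """Two populations x two samples over three markers."""
    values = np.array([
        [0, 0, 1],
        [0, 1, 1],
        [1, 1, 0],
        [0, 0, 1],
        [1, 1, 1],
        [1, 1, 0],
        [0, 1, 0],
        [0, 1, 1],
    ], dtype=np.uint8)
    return pp.HaplotypePanel(values, ["s1", "s2", "s3", "s4"],
                             ["popA", "popA", "popB", "popB"], make_snp_map(3))
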