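import os

os.environ.setdefault("MPLBACKEND", "Agg")

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from spathet import CNVMatrix

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20210703)


def make_bins(n, chrom="chr1", size=1_000_000):
    starts = np.arange(n) * size
    return pd.DataFrame({"chromosome": chrom, "start": starts,
                         "end": starts + size})


def make_matrix(values, labels="sample", chrom="chr1", prefix="c"):
    values = np.asarray(values)
    bins = make_bins(values.shape[1], chrom=chrom)
    cells = [f"{prefix}{i}" for i in range(values.shape[0])]
    return CNVMatrix(values, bins, cells, labels)


@pytest.fixture
def toy_matrix():
    """3 bins x 2 cells with CN {2,2,2; 2,4,2}."""
    return make_matrix(np.array([[2, 2, 2], [2, 4, 2]]))
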