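import numpy as np
import pandas as pd
import pytest

from mycoassembly.core import OtuTable, Phylogeny, SampleMetadata

#: three-tip tree used throughout: d(A,B)=2, d(A,C)=d(B,C)=4
SMALL_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def small_tree() -> Phylogeny:
    return Phylogeny.from_newick(SMALL_NEWICK)


@pytest.fixture
def small_table() -> OtuTable:
    counts = np.array([[3, 1, 0], [0, 2, 2], [1, 1, 1]])
    return OtuTable(counts, ["s1", "s2", "s3"], ["A", "B", "C"])


@pytest.fixture
def small_metadata() -> SampleMetadata:
    df = pd.DataFrame(
        {
            "host_species": ["h1", "h1", "h2"],
            "site": ["x", "x", "x"],
            "latitude": [40.0, 40.5, 41.0],
            "longitude": [115.0, 115.0, 115.0],
            "altitude": [800.0, 850.0, 900.0],
            "MAT": [8.0, 7.5, 7.0],
            "MAP": [420.0, 430.0, 440.0],
        },
        index=["s1", "s2", "s3"],
    )
    return SampleMetadata(df)


def random_otu_table(rng: np.random.Generator, n_samples: int, n_otus: int) -> OtuTable:
    counts = rng.integers(0, 20, size=(n_samples, n_otus))
    # keep every sample and OTU non-empty
    for i in range(n_samples):
        if counts[i].sum() == 0:
            counts[i, rng.integers(n_otus)] = 1
    keep = counts.sum(axis=0) > 0
    counts = counts[:, keep]
    return OtuTable(counts)
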