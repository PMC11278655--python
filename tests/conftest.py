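import numpy as np
import pandas as pd
import pytest

from nitronet.io_tables import RANKS, CountTable, SampleMetadata, TaxonomyMap


@pytest.fixture
def toy_table() -> CountTable:
    """4 samples x 5 OTUs with simple integer counts."""
    data = pd.DataFrame(
        [
            [10, 0, 3, 7, 0],
            [8, 1, 4, 6, 1],
            [0, 12, 0, 2, 6],
            [1, 10, 1, 1, 7],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["o1", "o2", "o3", "o4", "o5"],
    )
    return CountTable(data)


@pytest.fixture
def toy_taxonomy() -> TaxonomyMap:
    frame = pd.DataFrame(
        {
            "kingdom": ["Bacteria"] * 5,
            "phylum": ["P1", "P1", "P2", "P2", ""],
            "class": [""] * 5,
            "order": [""] * 5,
            "family": [""] * 5,
            "genus": ["g1", "g2", "g3", "g4", ""],
        },
        index=pd.Index(["o1", "o2", "o3", "o4", "o5"], name="otu_id"),
        columns=list(RANKS),
    )
    return TaxonomyMap(frame)


@pytest.fixture
def toy_metadata(toy_table) -> SampleMetadata:
    idx = toy_table.data.index
    return SampleMetadata(
        treatment=pd.Series(["A", "A", "B", "B"], index=idx),
        properties=pd.DataFrame(
            {"pH": [5.0, 5.2, 6.0, 6.1], "TN": [2.1, 2.0, 1.2, 1.1]}, index=idx
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_count_table(rng: np.random.Generator, n_samples=6, n_otus=8, depth=200) -> CountTable:
    p = rng.dirichlet(np.ones(n_otus), size=n_samples)
    counts = np.vstack([rng.multinomial(depth, row) for row in p])
    counts[:, 0] += 1  # guarantee positive totals
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"o{j}" for j in range(n_otus)],
        )
    )
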