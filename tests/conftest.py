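import numpy as np
import pandas as pd
import pytest

from conflux.datatypes import CountMatrix, SampleMeta


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 genes x 2 samples with easy arithmetic."""
    df = pd.DataFrame(
        {"s1": [5, 15, 30], "s2": [10, 30, 60]},
        index=pd.Index(["GA", "GB", "GC"], name="gene"),
    )
    return CountMatrix(df)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def random_counts(rng) -> CountMatrix:
    """50 genes x 6 samples of moderately dispersed counts."""
    genes = [f"G{i:03d}" for i in range(50)]
    samples = [f"s{j}" for j in range(6)]
    counts = rng.negative_binomial(5, 0.05, size=(50, 6))
    return CountMatrix(pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples))


@pytest.fixture
def paired_meta() -> SampleMeta:
    """Two specimens x two cultures x both lineages."""
    rows = []
    for spec in ("A", "B"):
        for culture in ("standard", "postconfluent"):
            for lineage in ("LEp", "MEp"):
                rows.append(
                    {
                        "sample_id": f"{spec}_{culture}_{lineage}",
                        "specimen": spec,
                        "lineage": lineage,
                        "culture": culture,
                    }
                )
    return SampleMeta(pd.DataFrame(rows).set_index("sample_id"))
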