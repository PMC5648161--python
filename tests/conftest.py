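import numpy as np
import pandas as pd
import pytest

from ampdisc import OtuTable, SampleMetadata, TaxonomyAnnotation


@pytest.fixture
def toy_table() -> OtuTable:
    """3 OTUs x 2 samples with easily hand-checked totals."""
    return OtuTable.from_arrays(
        ["otu1", "otu2", "otu3"],
        ["S1", "S2"],
        np.array([[100, 50], [1, 0], [0, 50]]),
        dataset_label="toy",
    )


@pytest.fixture
def four_group_metadata() -> SampleMetadata:
    """70 samples over the four study groups sized 23/15/10/22."""
    pairs = []
    i = 0
    for group, n in [
        ("upper_before", 23),
        ("upper_after", 15),
        ("middle_before", 10),
        ("lower_after", 22),
    ]:
        for _ in range(n):
            i += 1
            pairs.append((f"S{i:03d}", group))
    return SampleMetadata(pairs)


def make_table(counts, otu_ids=None, sample_ids=None, label="test") -> OtuTable:
    counts = np.asarray(counts)
    otu_ids = otu_ids or [f"otu{i+1}" for i in range(counts.shape[0])]
    sample_ids = sample_ids or [f"S{j+1}" for j in range(counts.shape[1])]
    return OtuTable.from_arrays(otu_ids, sample_ids, counts, label)


def annotation(otu_id, lineage=("Algae", "sp"), identity=95.0) -> TaxonomyAnnotation:
    return TaxonomyAnnotation(otu_id, tuple(lineage), identity)
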