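import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from asvpost import AsvRecord, Dataset, FeatureTable


def make_random_table(rng: np.random.Generator, max_features=10, max_samples=10):
    """A random small count table with a mix of big and tiny entries."""
    f = int(rng.integers(1, max_features + 1))
    s = int(rng.integers(1, max_samples + 1))
    counts = np.where(
        rng.random((f, s)) < 0.4,
        rng.integers(0, 6, size=(f, s)),          # crosstalk-sized noise
        rng.integers(0, 5000, size=(f, s)),       # real signal
    )
    return FeatureTable.from_arrays(
        counts, [f"F{i}" for i in range(f)], [f"S{j}" for j in range(s)]
    )


@pytest.fixture
def tiny_dataset() -> Dataset:
    """3 features x 2 samples with sequences, taxonomy and metadata."""
    table = FeatureTable.from_arrays(
        np.array([[10, 0], [5, 7], [0, 3]]),
        ["ASV_1", "ASV_2", "ASV_3"],
        ["SampleA", "SampleB"],
    )
    sequences = [
        AsvRecord("ASV_1", "ACGTACGTACGTACGT"),
        AsvRecord("ASV_2", "TTTTACGTACGTACGG"),
        AsvRecord("ASV_3", "GGGGACGTACGTACGC"),
    ]
    taxonomy = pd.DataFrame(
        {
            "Kingdom": ["Bacteria", "Bacteria", "Fungi"],
            "Phylum": ["Firmicutes", "Proteobacteria", "Ascomycota"],
            "Class": ["Bacilli", "Gammaproteobacteria", ""],
            "Order": ["", "Enterobacterales", ""],
            "Family": ["", "Enterobacteriaceae", ""],
            "Genus": ["", "Escherichia", ""],
            "Species": ["", "", ""],
        },
        index=pd.Index(["ASV_1", "ASV_2", "ASV_3"], name="#OTU ID"),
    )
    metadata = pd.DataFrame(
        {"group": ["early", "late"], "subject": ["m1", "m2"]},
        index=pd.Index(["SampleA", "SampleB"], name="#SampleID"),
    )
    return Dataset(
        table=table, sequences=sequences, taxonomy=taxonomy, metadata=metadata
    ).validate()
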