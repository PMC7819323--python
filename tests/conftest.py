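import numpy as np
import pytest

from viability_bench import AbundanceTable


@pytest.fixture
def counts_table() -> AbundanceTable:
    """3 taxa × 2 samples of integer counts."""
    return AbundanceTable(
        sample_ids=["s1", "s2"],
        taxon_ids=["otu1", "otu2", "otu3"],
        values=np.array([[10, 5, 0], [3, 0, 7]], dtype=float),
        mode="counts",
    )


@pytest.fixture
def taxonomy_table() -> AbundanceTable:
    """5 OTUs collapsing to 3 terminal clades (2 genera + 1 family)."""
    taxonomy = {
        "otu1": "k__Bacteria; p__Proteobacteria; f__Enterobacteriaceae; g__Escherichia",
        "otu2": "k__Bacteria; p__Proteobacteria; f__Enterobacteriaceae; g__Escherichia",
        "otu3": "k__Bacteria; p__Firmicutes; f__Streptococcaceae; g__Streptococcus",
        "otu4": "k__Bacteria; p__Proteobacteria; f__Enterobacteriaceae",
        "otu5": "k__Bacteria; p__Proteobacteria; f__Enterobacteriaceae; g__",
    }
    values = np.array(
        [
            [0.2, 0.3, 0.25, 0.15, 0.10],
            [0.05, 0.45, 0.30, 0.05, 0.15],
        ]
    )
    return AbundanceTable(
        sample_ids=["s1", "s2"],
        taxon_ids=list(taxonomy),
        values=values,
        mode="relative",
        taxonomy=taxonomy,
    )
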