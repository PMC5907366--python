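import numpy as np
import pytest

from mitodiag import Alignment, PartitionEntry, PartitionScheme, read_tree


@pytest.fixture
def toy_alignment():
    """2 genes x 2 taxa, annotated, with some missing data."""
    parts = PartitionScheme([PartitionEntry("g1", 0, 6),
                             PartitionEntry("g2", 6, 12)])
    gene, cpos = parts.annotate(12)
    return Alignment(
        ["tax1", "tax2", "tax3", "tax4"],
        np.array([list("ATGAAATTTGGG"),
                  list("ATGAAATTCGGG"),
                  list("ATAAAATTTGG-"),
                  list("ATGAA?TTTGGN")]),
        "DNA", gene, cpos), parts


@pytest.fixture
def quartet_tree():
    return read_tree("((t1:1,t2:1):1,(t3:1,t4:1):1);")


def random_alignment(rng, n_taxa, n_sites, missing_frac=0.05):
    chars = np.array(list("ACGT-N?"))
    p = [(1 - missing_frac) / 4] * 4 + [missing_frac / 3] * 3
    m = rng.choice(chars, size=(n_taxa, n_sites), p=p)
    return Alignment([f"t{i + 1:02d}" for i in range(n_taxa)], m)
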