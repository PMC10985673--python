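import numpy as np
import pytest

from lshtax.taxonomy import TaxonomyTree

# Hand-built 10-node fixture: external taxids equal internal IDs (sorted
# assignment), species S4 hangs directly under phylum P2 (missing ranks).
#
#   1 SK (superkingdom)
#   ├── 2 P1 (phylum)
#   │   └── 4 F1 (family)
#   │       ├── 5 G1 (genus)
#   │       │   ├── 6 S1 (species)
#   │       │   └── 7 S2 (species)
#   │       └── 8 G2 (genus)
#   │           └── 9 S3 (species)
#   └── 3 P2 (phylum)
#       └── 10 S4 (species)
FIXTURE_EDGES = [
    (1, 1, "superkingdom", "SK"),
    (2, 1, "phylum", "P1"),
    (3, 1, "phylum", "P2"),
    (4, 2, "family", "F1"),
    (5, 4, "genus", "G1"),
    (6, 5, "species", "S1"),
    (7, 5, "species", "S2"),
    (8, 4, "genus", "G2"),
    (9, 8, "species", "S3"),
    (10, 3, "species", "S4"),
]


@pytest.fixture
def fixture_tree() -> TaxonomyTree:
    return TaxonomyTree.from_edges(FIXTURE_EDGES)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_kmer_string(rng: np.random.Generator, k: int = 32) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))
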