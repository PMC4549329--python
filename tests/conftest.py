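import numpy as np
import pandas as pd
import pytest

from extirpa.trees import Phylogeny
from extirpa.synth import simulate_phylogeny


@pytest.fixture
def balanced4() -> Phylogeny:
    """Balanced 4-tip tree with unit branch lengths."""
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def tree50() -> Phylogeny:
    return simulate_phylogeny(50, seed=501)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture
def records_frame() -> pd.DataFrame:
    """Small hand-built occurrence table exercising the coding rules."""
    return pd.DataFrame(
        {
            "species_id": ["A", "A", "A", "B", "C", "C", "D"],
            "dataset": ["old", "old", "mon", "varia", "old", "mon", "coll"],
            "year": [1932, 1933, 2009, 1968, 1932, 2010, ""],
            "count": [3, 7, 4, 5, "", 2, 1],
            "abundance_text": ["", "", "", "", "abundant", "", ""],
        }
    )
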