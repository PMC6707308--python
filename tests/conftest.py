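import numpy as np
import pandas as pd
import pytest

from dilasm.containers import CommunityMatrix
from dilasm.trees import parse_newick

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree():
    """Three-tip tree with known patristic distances: d(A,B)=2, d(A,C)=d(B,C)=4."""
    return parse_newick(TOY_NEWICK)


@pytest.fixture
def toy_community():
    """Two disjoint single-taxon samples on the toy tree."""
    df = pd.DataFrame({"X": [1, 0, 0], "Y": [0, 0, 1]}, index=["A", "B", "C"])
    return CommunityMatrix(df, mode="counts")


def random_community(rng: np.random.Generator, tips, n_samples: int, mean_depth: int = 200):
    """Random sparse count table over the given tip labels."""
    cols = {}
    for i in range(n_samples):
        present = rng.random(len(tips)) < rng.uniform(0.3, 0.8)
        if not present.any():
            present[rng.integers(len(tips))] = True
        counts = np.where(present, rng.poisson(mean_depth / max(1, present.sum()), len(tips)) + 1, 0)
        cols[f"s{i}"] = counts * present
    return CommunityMatrix(pd.DataFrame(cols, index=tips), mode="counts").drop_empty_taxa()
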