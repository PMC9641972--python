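import io
import logging

import numpy as np
import pytest
from skbio import TreeNode

from ecoassembly import OtuTable

logging.getLogger("ecoassembly").setLevel(logging.ERROR)


@pytest.fixture
def small_table():
    """3 taxa x 4 samples with simple integer counts."""
    return OtuTable(
        ["A", "B", "C"],
        ["s1", "s2", "s3", "s4"],
        np.array([[1, 2, 0, 4], [3, 0, 5, 1], [0, 1, 1, 1]]),
    )


@pytest.fixture
def balanced_tree():
    """((A:1,B:1):1,(C:1,D:1):1); — cophenetic d(A,B)=2, d(A,C)=4."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_table(rng, n_taxa, n_samples, depth=500):
    p = rng.dirichlet(np.ones(n_taxa))
    counts = rng.multinomial(depth, p, size=n_samples).T
    # guarantee non-empty samples
    counts[0] += 1
    return OtuTable(
        [f"t{i}" for i in range(n_taxa)],
        [f"s{j}" for j in range(n_samples)],
        counts,
    )
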