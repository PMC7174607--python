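import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from cortree.io import CountTable


def random_binary_tree(rng: np.random.Generator, leaves: list[str]) -> TreeNode:
    """Uniform-ish random binary tree with exponential branch lengths."""

    def build(names):
        if len(names) == 1:
            return TreeNode(name=names[0], length=float(rng.exponential(1.0)))
        k = int(rng.integers(1, len(names)))
        left, right = names[:k], names[k:]
        node = TreeNode(length=float(rng.exponential(1.0)))
        node.extend([build(list(left)), build(list(right))])
        return node

    names = list(leaves)
    rng.shuffle(names)
    root = build(names)
    root.length = None
    return root


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[5, 0, 3, 7], [2, 2, 2, 2], [0, 9, 1, 4]],
        index=["taxA", "taxB", "taxC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return CountTable(counts)


@pytest.fixture
def grouped_table(rng):
    counts = pd.DataFrame(
        rng.negative_binomial(2, 0.05, size=(12, 20)),
        index=[f"t{i}" for i in range(12)],
        columns=[f"s{j}" for j in range(20)],
    )
    groups = pd.Series(["A"] * 10 + ["B"] * 10, index=counts.columns)
    return CountTable(counts, groups)
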