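from __future__ import annotations

import numpy as np
import pytest

from treeconsensus.tree_model import (
    Branch,
    Criterion,
    CriteriaSet,
    DecisionTree,
    Internal,
    Leaf,
    RecommendationSet,
)
from treeconsensus import synthetic


@pytest.fixture
def fitness_age() -> CriteriaSet:
    return CriteriaSet(
        [
            Criterion("fitness", ("fit", "unfit")),
            Criterion("age", ("<70", ">=70")),
        ]
    )


@pytest.fixture
def fitness_tree() -> DecisionTree:
    """Tests only fitness: fit -> chemo, unfit -> BSC."""
    root = Internal(
        "fitness",
        (
            Branch(("fit",), Leaf(RecommendationSet.single("chemo"))),
            Branch(("unfit",), Leaf(RecommendationSet.single("BSC"))),
        ),
    )
    return DecisionTree("centre-1", root)


@pytest.fixture
def single_leaf_tree() -> DecisionTree:
    return DecisionTree("centre-X", Leaf(RecommendationSet.single("X")))


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_criteria(rng: np.random.Generator, max_criteria: int = 4, max_levels: int = 3) -> CriteriaSet:
    n = int(rng.integers(1, max_criteria + 1))
    return synthetic.default_criteria(
        n, tuple(int(rng.integers(2, max_levels + 1)) for _ in range(n))
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return make_rng(20260903)
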