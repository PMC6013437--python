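import random

import dendropy
import numpy as np
import pandas as pd
import pytest

import mkhet
from mkhet.characters import CharacterMatrix


def make_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


@pytest.fixture
def four_tip_tree():
    return make_tree("((A:1.0,B:2.0)AB:1.0,(C:1.5,D:0.5)CD:2.0)root;")


@pytest.fixture
def small_matrix():
    df = pd.DataFrame(
        {"symmetry": [0, 1, 3, 2], "fusion": [1, 1, 0, 3]},
        index=["A", "B", "C", "D"],
    )
    return CharacterMatrix(df, label="test")


@pytest.fixture
def study_bundle():
    """A scaled-down five-partition synthetic dataset shared across tests."""
    cfg = mkhet.SimulationConfig(
        seed=20,
        partition_sizes={
            "ANA_Magnoliidae": 40,
            "Monocotyledoneae": 60,
            "basal_eudicots": 30,
            "Superrosidae": 70,
            "Superasteridae": 60,
        },
    )
    return mkhet.simulate_study(cfg)


@pytest.fixture
def study_scheme(study_bundle):
    return mkhet.PartitionScheme.from_clades(
        study_bundle.tree, list(study_bundle.config.partition_sizes)
    )


def random_column(rng: random.Random, idx, allow_uncertain=True):
    choices = [0, 1, 0, 1, 2, 3] if allow_uncertain else [0, 1]
    return {lab: rng.choice(choices) for lab in idx.tip_index}
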