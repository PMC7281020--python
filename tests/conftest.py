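import numpy as np
import pandas as pd
import pytest

from crossomics import (
    EvaluationConfig,
    GeneReactionMap,
    MetaboliteNetwork,
    Reaction,
    cohort_profiles,
    generate_dataset,
)
from crossomics.synthetic import SyntheticSpec


def make_network(rows):
    """rows: list of (reaction_id, substrates, products) with ids as strings."""
    return MetaboliteNetwork(
        Reaction(rid, frozenset(subs), frozenset(prods)) for rid, subs, prods in rows
    )


def random_network(rng, n_metabolites, n_reactions, max_side=2):
    mets = [f"m{i}" for i in range(n_metabolites)]
    rows = []
    for r in range(n_reactions):
        k = int(rng.integers(2, 2 * max_side + 1))
        picks = rng.choice(n_metabolites, size=min(k, n_metabolites), replace=False)
        split = max(1, k // 2)
        rows.append(
            (f"r{r}", {mets[i] for i in picks[:split]}, {mets[i] for i in picks[split:]})
        )
    return make_network(rows)


@pytest.fixture
def chain_network():
    """Linear chain a-b-c-d-e through four reactions."""
    return make_network(
        [
            ("r1", {"a"}, {"b"}),
            ("r2", {"b"}, {"c"}),
            ("r3", {"c"}, {"d"}),
            ("r4", {"d"}, {"e"}),
        ]
    )


@pytest.fixture
def reaction_frame():
    return pd.DataFrame(
        [
            {"reaction_id": "r1", "substrates": "A", "products": "B"},
            {"reaction_id": "r2", "substrates": "B", "products": "C"},
        ]
    )


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down synthetic study used by most integration tests."""
    return SyntheticSpec(
        n_metabolites=80,
        n_reactions=60,
        n_genes=40,
        n_controls=12,
        n_patients=6,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_dataset):
    return cohort_profiles(small_dataset)


@pytest.fixture(scope="session")
def small_eval_config(small_dataset):
    return EvaluationConfig(
        n_background=len(small_dataset.gene_map) - 1,
        n_repetitions=4,
        n_test=3,
        n_splits=3,
        seed=7,
    )
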