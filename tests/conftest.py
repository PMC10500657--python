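"""Shared fixtures: small graphs and trained spaces reused across test modules."""

import numpy as np
import pytest

import chemkgqa as c


@pytest.fixture()
def chain_kg():
    """a -> b -> c via r1, r2."""
    kg = c.KnowledgeGraph()
    kg.add_triple("a", "r1", "b")
    kg.add_triple("b", "r2", "cc")
    return kg


@pytest.fixture(scope="session")
def small_planted():
    """An 80-entity planted graph: (full_kg, truth, train_kg)."""
    cfg = c.SyntheticConfig(n_entities=80, n_relations=5, n_deep_chains=4,
                            n_attributes=2, seed=11)
    kg, truth = c.generate_planted_kg(cfg)
    return kg, truth, truth.make_train_kg(kg)


@pytest.fixture(scope="session")
def small_trained_space(small_planted):
    """A TransEA space trained briefly on the small planted graph."""
    _, _, train = small_planted
    return c.train_embeddings(train, "TransEA",
                              c.TrainingConfig(epochs=150, seed=3))


@pytest.fixture(scope="session")
def default_planted():
    """The default study-condition graph: 200 entities, 8 relations, sigma=0.05."""
    kg, truth = c.generate_planted_kg(c.SyntheticConfig(seed=0))
    return kg, truth, truth.make_train_kg(kg)


def random_kg(rng: np.random.Generator, n_entities=20, n_relations=3, n_triples=40,
              n_attributes=2, n_attr_triples=15) -> c.KnowledgeGraph:
    """A uniformly random (unplanted) graph for oracle comparisons."""
    kg = c.KnowledgeGraph(ontology_label="random")
    ents = [f"e{i}" for i in range(n_entities)]
    rels = [f"r{i}" for i in range(n_relations)]
    for _ in range(n_triples):
        h, t = rng.choice(n_entities, size=2, replace=False)
        kg.add_triple(ents[int(h)], rels[int(rng.integers(n_relations))], ents[int(t)])
    for _ in range(n_attr_triples):
        kg.add_attribute(ents[int(rng.integers(n_entities))],
                         f"a{int(rng.integers(n_attributes))}",
                         float(rng.normal()), "u")
    return kg
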