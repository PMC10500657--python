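"""Synthetic knowledge graphs and question sets with planted structure.

The generator emulates the statistical shape of desk-scale chemistry
ontologies so that every pipeline stage is testable without external data:

* **Planted translation geometry.**  Entities carry latent vectors; each
  relation connects a head cluster to a tail cluster whose centers differ by
  the relation's latent translation, so a translation-based embedding can
  recover the structure.  A configurable fraction of relations is 1-to-N
  with truncated-geometric fan-out (mimicking the heavy imbalance of real
  reaction ontologies, where a common species joins thousands of reactions
  and a rare one a handful).
* **Numeric attributes.**  Attribute values are linear reads of the latent
  vectors, ``v = z . l* + b* + noise``, the generative model the joint
  attribute embedding assumes.
* **Deep chains.**  Species whose answer value sits ``depth`` hops away
  (species -> calculation -> result -> value), the structure that motivates
  implicit multihop relation derivation; chain-node latents follow the step
  translations exactly.
* **Questions.**  Template-generated relation questions over held-out
  triples, numeric filter questions, and mention-labeled texts with optional
  single-character misspellings for entity-linking tests.  Train/test
  template sets can be kept disjoint.

Everything is reproducible from ``SyntheticConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .embedding import EmbeddingSpace, TrainingConfig
from .kg import COMPOSITE_SEPARATOR, KnowledgeGraph, Triple

__all__ = ["SyntheticConfig", "GroundTruth", "GeneratedQuestion",
           "generate_planted_kg", "generate_questions", "generate_ontologies"]

_SYLLABLES = ["meth", "eth", "prop", "but", "pent", "hex", "benz", "chlor",
              "fluor", "brom", "ox", "hydro", "cycl", "sulf", "nitr", "carb",
              "phen", "acet", "form", "glyc"]
_SUFFIXES = ["ane", "ene", "yne", "ol", "al", "one", "ate", "ium", "ide", "ine"]
_UNITS = ["g/mol", "K", "kJ/mol", "Pa", "nm"]


@dataclass
class SyntheticConfig:
    """Knobs of the planted-structure generator.

    Defaults give a desk-scale graph of 200 entities and 8 relations with 3
    numeric attributes observed under noise ``sigma = 0.05``, half the
    relations densely 1-to-N with mean fan-out ~6 (real species/reaction
    ontologies are far denser still), and 10 deep 3-hop chains.
    """

    n_entities: int = 200
    n_relations: int = 8
    one_to_n_fraction: float = 0.5
    mean_fanout: float = 6.0
    n_attributes: int = 3
    attribute_coverage: float = 0.9
    sigma: float = 0.05
    n_deep_chains: int = 10
    chain_depth: int = 3
    n_ontologies: int = 1
    dimension: int = 32          # latent dimension; matches the trainer default
    geometry_jitter: float = 0.15
    test_fraction: float = 0.2
    perturbation_rate: float = 0.0
    ontology_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_entities, self.n_relations, self.dimension) < 1:
            raise ValueError("counts must be positive")
        if self.n_deep_chains and self.chain_depth < 2:
            raise ValueError("chain depth must be >= 2")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not 0 <= self.test_fraction < 1:
            raise ValueError("test_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator planted: latents, splits, and gold answers."""

    latents: dict[str, np.ndarray]
    relation_translations: dict[str, np.ndarray]
    attribute_maps: dict[str, tuple[np.ndarray, float]]   # l*, b*
    attribute_values: dict[tuple[str, str], float]        # noiseless values
    train_triples: list[Triple]
    test_triples: list[Triple]
    chain_gold: dict[str, str]                            # species -> leaf entity
    chain_relations: list[str]
    relation_words: dict[str, str]
    attribute_words: dict[str, str]
    attribute_units: dict[str, str]

    def make_train_kg(self, kg: KnowledgeGraph) -> KnowledgeGraph:
        """The training graph: all vocabulary, train triples only.

        Entities and relations are interned in full-graph order first so the
        train graph shares ids with the full graph.
        """
        train = KnowledgeGraph(ontology_label=kg.ontology_label)
        for e in kg.entities:
            train._intern_entity(e)
        for r in kg.relations:
            train._intern_relation(r)
        for t in self.train_triples:
            train.add_triple(*t)
        for a in sorted(kg.attribute_triples):
            train.add_attribute(*a)
        for iri, lab in kg.labels.items():
            train.set_label(iri, lab.label, lab.type_tag, lab.aliases)
        train.validate()
        return train

    def exact_space(self, kg: KnowledgeGraph, method: str = "TransE") -> EmbeddingSpace:
        """An embedding space built from the planted latents.

        Chain triples satisfy ``t = h + r`` exactly, so the space is exact on
        them; composite relations (from multihop derivation) get the sum of
        their step translations.
        """
        d = len(next(iter(self.latents.values())))
        E = np.stack([self.latents[e] for e in kg.entities])
        R = np.zeros((kg.n_relations, d))
        for i, rel in enumerate(kg.relations):
            if COMPOSITE_SEPARATOR in rel:
                total = np.zeros(d)
                for part in rel.split(COMPOSITE_SEPARATOR):
                    inv = part.startswith("^")
                    t = self.relation_translations[part.lstrip("^")]
                    total += -t if inv else t
                R[i] = total
            else:
                R[i] = self.relation_translations[rel]
        L = b = None
        if kg.attributes:
            L = np.stack([self.attribute_maps[a][0] for a in kg.attributes])
            b = np.array([self.attribute_maps[a][1] for a in kg.attributes])
        return EmbeddingSpace(
            method=method, dimension=d,
            entity_vocab=list(kg.entities), relation_vocab=list(kg.relations),
            attribute_vocab=list(kg.attributes),
            entity_embeddings=E, relation_embeddings=R,
            attribute_vectors=L, attribute_bias=b,
            config=TrainingConfig(dimension=d, squared_distance=False, epochs=0),
            ontology_label=kg.ontology_label,
        )


def _make_name(rng: np.random.Generator, taken: set[str]) -> str:
    for _ in range(100):
        n = 2 + int(rng.integers(2))
        name = "".join(rng.choice(_SYLLABLES) for _ in range(n)) + str(rng.choice(_SUFFIXES))
        if name not in taken:
            taken.add(name)
            return name
    raise RuntimeError("name space exhausted")


def _make_word(rng: np.random.Generator, taken: set[str]) -> str:
    # short pronounceable property/relation word, e.g. "oxcarbate"
    return _make_name(rng, taken)


def _ball(rng: np.random.Generator, d: int, radius: float) -> np.ndarray:
    v = rng.normal(size=d)
    v /= np.linalg.norm(v)
    return v * radius * rng.uniform() ** (1.0 / d)


def generate_planted_kg(config: SyntheticConfig) -> tuple[KnowledgeGraph, GroundTruth]:
    """Generate one ontology with planted geometry; see the module docstring.

    Returns the full graph (train + held-out triples) and the ground truth;
    use :meth:`GroundTruth.make_train_kg` for the training split.  Raises on
    infeasible configurations (e.g. chains or fan-out exceeding the entity
    budget).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    d = cfg.dimension

    n_chain_nodes = cfg.n_deep_chains * cfg.chain_depth
    n_species = cfg.n_deep_chains
    n_core = cfg.n_entities - n_chain_nodes - n_species
    n_chain_rel = cfg.chain_depth if cfg.n_deep_chains else 0
    n_cluster_rel = cfg.n_relations - n_chain_rel
    if n_core < 4 * max(n_cluster_rel, 1) or n_cluster_rel < 1:
        raise ValueError(
            f"infeasible config: {cfg.n_entities} entities cannot host "
            f"{cfg.n_deep_chains} chains of depth {cfg.chain_depth} plus "
            f"{n_cluster_rel} cluster relations"
        )

    taken: set[str] = set()
    name_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    rel_words = [_make_word(name_rng, taken) for _ in range(cfg.n_relations)]
    attr_words = [_make_word(name_rng, taken) for _ in range(cfg.n_attributes)]

    chain_rels = [f"rel:{w}" for w in rel_words[:n_chain_rel]]
    cluster_rels = [f"rel:{w}" for w in rel_words[n_chain_rel:]]
    attributes = [f"attr:{w}" for w in attr_words]
    relation_words = dict(zip(chain_rels + cluster_rels, rel_words))
    attribute_words = dict(zip(attributes, attr_words))
    attribute_units = {a: _UNITS[i % len(_UNITS)] for i, a in enumerate(attributes)}

    kg = KnowledgeGraph(ontology_label=cfg.ontology_label)
    latents: dict[str, np.ndarray] = {}
    translations: dict[str, np.ndarray] = {}
    train: list[Triple] = []
    test: list[Triple] = []

    # -- cluster relations over core entities ------------------------------
    core = [f"{cfg.ontology_label}:e{i}" for i in range(n_core)]
    per_cluster = n_core // (2 * n_cluster_rel)
    clusters = [core[i * per_cluster:(i + 1) * per_cluster]
                for i in range(2 * n_cluster_rel)]
    for j, leftover in enumerate(core[2 * n_cluster_rel * per_cluster:]):
        clusters[j % (2 * n_cluster_rel)].append(leftover)

    n_one_to_n = round(cfg.one_to_n_fraction * n_cluster_rel)
    geo_p = 1.0 / cfg.mean_fanout
    for k, rel in enumerate(cluster_rels):
        heads, tails = clusters[2 * k], clusters[2 * k + 1]
        c_h, c_t = _ball(rng, d, 0.6), _ball(rng, d, 0.6)
        translations[rel] = c_t - c_h
        for ent in heads:
            latents.setdefault(ent, c_h + _ball(rng, d, cfg.geometry_jitter))
        # edges first; tails are then placed consistently with the planted
        # translation of their actual heads, so the geometry encodes the edges
        triples: list[Triple] = []
        if k < n_one_to_n:
            for h in heads:
                # real 1-to-N relations are dense; keep every head on >= 2 edges
                fan = min(max(int(rng.geometric(geo_p)), 2), len(tails))
                chosen = rng.choice(len(tails), size=fan, replace=False)
                triples += [Triple(h, rel, tails[int(c)]) for c in chosen]
        else:
            perm = rng.permutation(len(tails))
            triples += [Triple(h, rel, tails[int(perm[i % len(tails)])])
                        for i, h in enumerate(heads)]
        # every tail of a 1-to-N relation gets in-degree >= 2, so held-out
        # edges leave both endpoints trainable
        min_in = 2 if k < n_one_to_n else 1
        in_deg = {t_ent: sum(t.tail == t_ent for t in set(triples)) for t_ent in tails}
        for t_ent in tails:
            while in_deg[t_ent] < min_in:
                h = heads[int(rng.integers(len(heads)))]
                cand = Triple(h, rel, t_ent)
                if cand not in triples:
                    triples.append(cand)
                    in_deg[t_ent] += 1
        triples = sorted(set(triples))
        heads_of: dict[str, list[str]] = {}
        for t in triples:
            heads_of.setdefault(t.tail, []).append(t.head)
        for t_ent in tails:
            anchor = np.mean([latents[h] for h in heads_of[t_ent]], axis=0)
            latents.setdefault(
                t_ent,
                anchor + translations[rel] + _ball(rng, d, cfg.geometry_jitter / 3.0),
            )
        # hold out only edges whose head keeps another edge and whose tail
        # keeps another in-edge, so the training vocabulary stays complete
        rng.shuffle(triples)
        head_deg = {h: sum(t.head == h for t in triples) for h in heads}
        tail_deg = {t_: sum(t.tail == t_ for t in triples) for t_ in tails}
        n_test = int(cfg.test_fraction * len(triples))
        held = []
        for t in triples:
            if len(held) < n_test and head_deg[t.head] > 1 and tail_deg[t.tail] > 1:
                held.append(t)
                head_deg[t.head] -= 1
                tail_deg[t.tail] -= 1
            else:
                train.append(t)
        test += held

    # -- deep chains -------------------------------------------------------
    chain_gold: dict[str, str] = {}
    for rel in chain_rels:
        translations[rel] = _ball(rng, d, 0.4)
    for c in range(cfg.n_deep_chains):
        species = f"{cfg.ontology_label}:species{c}"
        z = _ball(rng, d, 0.5)
        latents[species] = z
        prev = species
        for depth, rel in enumerate(chain_rels):
            node = (f"{cfg.ontology_label}:chain{c}_n{depth}"
                    if depth < cfg.chain_depth - 1
                    else f"{cfg.ontology_label}:value{c}")
            z = z + translations[rel]
            latents[node] = z.copy()
            train.append(Triple(prev, rel, node))
            prev = node
        chain_gold[species] = prev

    for t in train + test:
        kg.add_triple(*t)

    # -- labels ------------------------------------------------------------
    label_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    for ent in kg.entities:
        name = _make_name(label_rng, taken)
        formula = ("C" + str(1 + int(label_rng.integers(9)))
                   + "H" + str(1 + int(label_rng.integers(20))))
        tag = "species" if ":species" in ent or ":e" in ent else "node"
        kg.set_label(ent, name, tag, (formula,))

    # -- numeric attributes ------------------------------------------------
    attr_maps: dict[str, tuple[np.ndarray, float]] = {}
    attr_values: dict[tuple[str, str], float] = {}
    n_covered = int(cfg.attribute_coverage * kg.n_entities)
    for a in attributes:
        l_star = rng.normal(size=d) / np.sqrt(d)
        b_star = float(rng.uniform(-0.5, 0.5))
        attr_maps[a] = (l_star, b_star)
        chosen = sorted(rng.choice(kg.n_entities, size=n_covered, replace=False))
        for idx in chosen:
            ent = kg.entities[int(idx)]
            v_true = float(latents[ent] @ l_star + b_star)
            attr_values[(ent, a)] = v_true
            v_obs = v_true + (rng.normal(0.0, cfg.sigma) if cfg.sigma > 0 else 0.0)
            kg.add_attribute(ent, a, v_obs, attribute_units[a])

    kg.validate()
    truth = GroundTruth(
        latents=latents,
        relation_translations=translations,
        attribute_maps=attr_maps,
        attribute_values=attr_values,
        train_triples=sorted(train),
        test_triples=sorted(test),
        chain_gold=chain_gold,
        chain_relations=chain_rels,
        relation_words=relation_words,
        attribute_words=attribute_words,
        attribute_units=attribute_units,
    )
    return kg, truth


def generate_ontologies(config: SyntheticConfig) -> list[tuple[KnowledgeGraph, GroundTruth]]:
    """Generate ``n_ontologies`` independent graphs with disjoint vocabularies."""
    out = []
    for i in range(config.n_ontologies):
        sub = replace(config, seed=config.seed + 1000 * i,
                      ontology_label=f"{config.ontology_label}{i}"
                      if config.n_ontologies > 1 else config.ontology_label)
        out.append(generate_planted_kg(sub))
    return out


# ---------------------------------------------------------------------------
# Question generation


@dataclass
class GeneratedQuestion:
    """A question with its gold answers and entity-linking annotations."""

    text: str
    head_entity: str
    relation: str | None
    gold_entities: list[str]
    mention: str
    mention_span: tuple[int, int]
    numeric: bool = False
    operator: str | None = None
    value: float | None = None
    unit: str = ""
    template_id: int = 0


_RELATION_TEMPLATES = [
    "what is the {relation} of {head}?",
    "which entity is the {relation} of {head}?",
    "find the {relation} of {head}",
    "tell me the {relation} of the species {head}",
    "for {head}, what is its {relation}?",
    "{head} has which {relation}?",
]

_NUMERIC_TEMPLATES = [
    "which species have a {attribute} {operator} {value} {unit}?",
    "list all species with {attribute} {operator} {value} {unit}",
]

_OPERATOR_TEXT = {"larger": "larger than", "smaller": "smaller than",
                  "close": "close to"}


def _perturb(word: str, rng: np.random.Generator) -> str:
    """One random character edit (substitute, delete, or insert)."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    op = int(rng.integers(3))
    pos = int(rng.integers(len(word)))
    ch = letters[int(rng.integers(26))]
    if op == 0:
        return word[:pos] + ch + word[pos + 1:]
    if op == 1 and len(word) > 2:
        return word[:pos] + word[pos + 1:]
    return word[:pos] + ch + word[pos:]


def generate_questions(
    kg: KnowledgeGraph,
    truth: GroundTruth,
    config: SyntheticConfig,
    n_numeric: int = 20,
    split_templates: bool = False,
) -> list[GeneratedQuestion]:
    """Instantiate question templates over the held-out triples.

    Every question is answerable from the graph (golds verified present).
    With ``split_templates`` the even-indexed templates are reserved for
    training-time use and only odd-indexed ones are used here, so question
    structures at test time are unseen.  Mentions are the head labels,
    perturbed by one character edit at ``config.perturbation_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    templates = list(enumerate(_RELATION_TEMPLATES))
    if split_templates:
        templates = [(i, t) for i, t in templates if i % 2 == 1]
    out: list[GeneratedQuestion] = []

    by_head_rel: dict[tuple[str, str], list[str]] = {}
    for h, r, t in truth.test_triples:
        by_head_rel.setdefault((h, r), []).append(t)
    for (h, r), golds in sorted(by_head_rel.items()):
        tid, tpl = templates[int(rng.integers(len(templates)))]
        word = truth.relation_words[r]
        mention = kg.labels[h].label
        if config.perturbation_rate > 0 and rng.uniform() < config.perturbation_rate:
            mention = _perturb(mention, rng)
        text = tpl.format(relation=word, head=mention)
        start = text.index(mention)
        out.append(GeneratedQuestion(
            text=text, head_entity=h, relation=r, gold_entities=sorted(golds),
            mention=mention, mention_span=(start, start + len(mention)),
            template_id=tid,
        ))

    stored: dict[str, list[tuple[str, float]]] = {}
    for e, a, v, _ in kg.attribute_triples:
        stored.setdefault(a, []).append((e, v))
    for i in range(n_numeric):
        a = kg.attributes[int(rng.integers(len(kg.attributes)))] if kg.attributes else None
        if a is None:
            break
        vals = stored.get(a, [])
        if not vals:
            continue
        op = ("larger", "smaller", "close")[i % 3]
        pivot = round(float(vals[int(rng.integers(len(vals)))][1]), 4)
        tau = 0.05 * abs(pivot) if pivot else 0.05
        if op == "larger":
            gold = sorted(e for e, v in vals if v > pivot)
        elif op == "smaller":
            gold = sorted(e for e, v in vals if v < pivot)
        else:
            gold = sorted(e for e, v in vals if abs(v - pivot) <= tau)
        tpl = _NUMERIC_TEMPLATES[i % len(_NUMERIC_TEMPLATES)]
        text = tpl.format(attribute=truth.attribute_words[a],
                          operator=_OPERATOR_TEXT[op],
                          value=round(pivot, 4), unit=truth.attribute_units[a])
        out.append(GeneratedQuestion(
            text=text, head_entity="", relation=a, gold_entities=gold,
            mention="", mention_span=(0, 0), numeric=True, operator=op,
            value=pivot, unit=truth.attribute_units[a],
        ))
    return out


def generate_alignment_benchmark(
    seed: int = 0,
    n_questions: int = 60,
    scale_mismatch: float = 10.0,
    n_per_engine: int = 5,
):
    """A constructed scale-mismatch benchmark for score alignment.

    Two QA engines answer every question.  The gold answer always comes from
    engine A, whose raw similarity scores live on a unit scale; engine B
    returns junk whose scores are ``scale_mismatch`` times larger.  Question
    texts carry engine-A-affiliated vocabulary, so an alignment model can
    learn to favor A from the question, while plain max normalization erases
    the scale difference and leaves gold tied with B's top junk answer.

    Returns ``(train_examples, test_examples)`` of
    :class:`~chemkgqa.alignment.AlignmentExample`.
    """
    from .alignment import AlignmentExample
    from .qa import ScoredCandidate

    rng = np.random.default_rng(seed)
    words_a = ["solubility", "weight", "boiling", "melting", "density"]
    words_b = ["orbital", "gaussian", "frequency", "basis", "functional"]
    examples = []
    for i in range(n_questions):
        w = words_a[int(rng.integers(len(words_a)))]
        question = f"what is the {w} of species {i}?"
        gold = f"A:gold{i}"
        a_scores = np.sort(rng.uniform(0.3, 0.9, size=n_per_engine))[::-1]
        a_cands = [ScoredCandidate(entity=gold, score=float(a_scores[0] + 0.1),
                                   normalized_score=float(a_scores[0] + 0.1),
                                   ontology_label="ontoA")]
        a_cands += [ScoredCandidate(entity=f"A:d{i}_{j}", score=float(s),
                                    normalized_score=float(s), ontology_label="ontoA")
                    for j, s in enumerate(a_scores[1:])]
        b_scores = rng.uniform(0.3, 1.0, size=n_per_engine) * scale_mismatch
        b_cands = [ScoredCandidate(entity=f"B:j{i}_{j}", score=float(s),
                                   normalized_score=float(s), ontology_label="ontoB")
                   for j, s in enumerate(b_scores)]
        examples.append(AlignmentExample(
            question=question, gold_entity=gold, gold_ontology="ontoA",
            answers={"ontoA": a_cands, "ontoB": b_cands}))
    cut = int(0.7 * n_questions)
    return examples[:cut], examples[cut:]


def relation_templates(truth: GroundTruth) -> dict[str, list[str]]:
    """The template set for the keyword relation predictor, per relation IRI."""
    return {
        rel: [t.format(relation=word, head="{head}") for t in _RELATION_TEMPLATES]
        for rel, word in truth.relation_words.items()
    }
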