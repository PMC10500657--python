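"""Per-ontology question-answering workflow over one embedding space.

Pipeline for a question ``q``: (1) link the head-entity mention to its IRI
with a fuzzy name search over labels, formulas and aliases; (2) map the
question to a relation embedding (template matching by default; any
callable predictor plugs in); (3) let the subgraph agent collect candidate
answers within ``n`` hops of the head; (4) score each hypothetical triple
``(h, r_hat, a')`` with the space's score function and keep the top ``k``;
(5) attach numeric literals via the lateral lookup agent.

Numerical questions ("which species have a molecular weight less than
50 g/mol?") go through two rounds of filtering: round 1 keeps entities whose
*predicted* attribute value ``v_hat = e . l + b`` satisfies the operator with
a recall slack ``delta``; round 2 keeps survivors whose *actual* stored value
satisfies it exactly.  Entities with no stored value are reported separately
rather than silently dropped.  Units are compared as literal strings after
whitespace normalization; no unit conversion is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .embedding import EmbeddingSpace
from .kg import EntityNotFound, KnowledgeGraph

__all__ = [
    "QuestionSpec", "ScoredCandidate", "NumericQualifier", "NumericFilterResult",
    "UnresolvedRelation", "UnresolvedOperator",
    "link_entity_fuzzy", "TemplateRelationPredictor", "predict_relation_embedding",
    "parse_numeric_operator", "answer", "numeric_filter_answer", "default_slack",
]

OPERATORS = ("larger", "smaller", "close")


class UnresolvedRelation(Exception):
    """No template or relation IRI could be matched to the question."""


class UnresolvedOperator(Exception):
    """A number was found but its comparison qualifier was not recognized."""


@dataclass(frozen=True)
class NumericQualifier:
    operator: str
    value: float
    unit: str = ""
    tolerance: float | None = None  # for "close"; default 5% of |value|

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")

    @property
    def tau(self) -> float:
        if self.tolerance is not None:
            return self.tolerance
        return 0.05 * abs(self.value) if self.value else 0.05


@dataclass
class QuestionSpec:
    """A structured query: head + relation + optional numeric filter."""

    question_text: str | None = None
    head_entity: str | None = None
    relation: str | None = None
    numeric_filter: NumericQualifier | None = None
    hop_limit: int = 3
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.question_text is None and self.head_entity is None:
            raise ValueError("need question_text or head_entity")
        if self.top_k < 1 or self.hop_limit < 1:
            raise ValueError("top_k and hop_limit must be >= 1")


@dataclass
class ScoredCandidate:
    """One ranked answer with its raw and polarity-normalized scores."""

    entity: str
    score: float
    normalized_score: float  # higher = better regardless of method
    ontology_label: str
    numeric_values: dict[str, tuple[float, str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Fuzzy entity linking


def _normalize(text: str) -> str:
    return " ".join(text.lower().split())


def string_similarity(a: str, b: str) -> float:
    """Levenshtein similarity normalized to [0, 1] (1.0 = exact match)."""
    a, b = _normalize(a), _normalize(b)
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def link_entity_fuzzy(
    mention_or_question: str,
    kg: KnowledgeGraph,
    threshold: float = 0.6,
) -> list[tuple[str, float, str]]:
    """Rank entities by fuzzy name similarity to a mention.

    Matches against every name in the label table (primary labels, chemical
    formulas carried as aliases, and all other aliases).  When the input is a
    longer question rather than a clean mention, word n-grams of the question
    are tried as candidate mentions.  Returns ``(entity IRI, similarity,
    matched label)`` tuples sorted by descending similarity with ties broken
    by entity id; an empty list is the explicit no-match result.
    """
    names: list[tuple[str, str]] = []
    for iri, lab in kg.labels.items():
        for name in lab.all_names():
            names.append((name, iri))
    text = _normalize(mention_or_question)
    fragments = {text}
    words = text.split()
    if len(words) > 1:
        for n in range(1, min(4, len(words)) + 1):
            for i in range(len(words) - n + 1):
                fragments.add(" ".join(words[i:i + n]).strip("?.,;:!"))
    fragments = {f for f in fragments if f}

    best: dict[str, tuple[float, str]] = {}
    for name, iri in names:
        sim = max(string_similarity(frag, name) for frag in fragments)
        if iri not in best or sim > best[iri][0]:
            best[iri] = (sim, name)
    hits = [(iri, sim, name) for iri, (sim, name) in best.items() if sim >= threshold]
    hits.sort(key=lambda x: (-x[1], kg.entity_id[x[0]]))
    return hits


# ---------------------------------------------------------------------------
# Relation prediction


class TemplateRelationPredictor:
    """Template/keyword relation predictor.

    Built from a template set mapping each relation IRI to question templates
    with ``{head}`` (and optionally ``{value}``/``{unit}``) placeholders, e.g.
    ``"how much does it weigh?"`` for a weight relation.  A question matching
    a template (placeholders wildcarded) resolves to that relation; otherwise
    the most similar template above ``fuzzy_threshold`` wins.  This is the
    pluggable contract a learned question-to-relation model would fill.
    """

    _PLACEHOLDER = re.compile(r"\{(head|value|unit)\}")

    def __init__(self, templates: dict[str, list[str]], fuzzy_threshold: float = 0.55):
        self.templates = {r: list(ts) for r, ts in templates.items()}
        self.fuzzy_threshold = fuzzy_threshold
        self._compiled: list[tuple[re.Pattern, str]] = []
        for rel in sorted(self.templates):
            for tpl in self.templates[rel]:
                pattern = self._PLACEHOLDER.sub("\x00", _normalize(tpl))
                pattern = re.escape(pattern).replace("\x00", ".+?")
                self._compiled.append((re.compile(f"^{pattern}$"), rel))

    def predict(self, question_text: str) -> str:
        """Return the relation IRI for a question, or raise :class:`UnresolvedRelation`."""
        q = _normalize(question_text)
        for pattern, rel in self._compiled:
            if pattern.match(q):
                return rel
        best_rel, best_sim = None, 0.0
        for rel in sorted(self.templates):
            for tpl in self.templates[rel]:
                sim = string_similarity(q, self._PLACEHOLDER.sub("", _normalize(tpl)))
                if sim > best_sim:
                    best_rel, best_sim = rel, sim
        if best_rel is None or best_sim < self.fuzzy_threshold:
            raise UnresolvedRelation(question_text)
        return best_rel


def predict_relation_embedding(
    question_text: str,
    kg: KnowledgeGraph,
    space: EmbeddingSpace,
    predictor: TemplateRelationPredictor,
) -> tuple[str, np.ndarray]:
    """Map a question to (relation IRI, its exact embedding row)."""
    rel = predictor.predict(question_text)
    if rel not in space.relation_id:
        raise UnresolvedRelation(f"predicted relation {rel!r} absent from the space")
    return rel, space.relation_embeddings[space.relation_id[rel]]


# ---------------------------------------------------------------------------
# Numeric qualifier parsing

_NUMBER = r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?"
_UNIT = r"[^\s?.,;:!]*"
_OPERATOR_PATTERNS = [
    (re.compile(rf"(?:larger|greater|bigger|more|higher)\s+than\s+({_NUMBER})\s*({_UNIT})", re.I), "larger"),
    (re.compile(rf"(?:above|over|exceeding)\s+({_NUMBER})\s*({_UNIT})", re.I), "larger"),
    (re.compile(rf"(?:smaller|less|lower|fewer)\s+than\s+({_NUMBER})\s*({_UNIT})", re.I), "smaller"),
    (re.compile(rf"(?:below|under)\s+({_NUMBER})\s*({_UNIT})", re.I), "smaller"),
    (re.compile(rf"(?:close\s+to|around|approximately|near|about)\s+({_NUMBER})\s*({_UNIT})", re.I), "close"),
    (re.compile(rf"\bat\s+({_NUMBER})\s*({_UNIT})", re.I), "close"),
]
# a free-standing number; digits embedded in identifiers (formulas like
# C3H4O, IRIs) do not count
_ANY_NUMBER = re.compile(rf"(?<![A-Za-z0-9_./]){_NUMBER}(?![A-Za-z0-9])")


def parse_numeric_operator(question_text: str) -> NumericQualifier | None:
    """Extract the first numeric qualifier: operator, value, trailing unit.

    Recognized operator families map onto ``larger`` / ``smaller`` / ``close``
    ("at 100 K" counts as close).  Returns ``None`` when the question carries
    no number; raises :class:`UnresolvedOperator` when a number is present but
    no qualifier around it is recognized.
    """
    matches = []
    for pattern, op in _OPERATOR_PATTERNS:
        m = pattern.search(question_text)
        if m:
            matches.append((m.start(), op, m))
    if matches:
        _, op, m = min(matches, key=lambda x: x[0])
        return NumericQualifier(op, float(m.group(1)), m.group(2).strip())
    if _ANY_NUMBER.search(question_text):
        raise UnresolvedOperator(question_text)
    return None


# ---------------------------------------------------------------------------
# Answering


def answer(
    spec: QuestionSpec,
    kg: KnowledgeGraph,
    space: EmbeddingSpace,
    predictor: TemplateRelationPredictor | None = None,
    direction: str = "both",
    link_threshold: float = 0.6,
) -> list[ScoredCandidate]:
    """Answer a structured or textual question against one embedding space.

    Candidate answers are the n-hop neighborhood of the head (undirected by
    default, since answers in deep ontologies may sit on inverse paths); each
    is scored as the tail of the hypothetical triple ``(h, r_hat, a')``.
    Returns at most ``spec.top_k`` candidates, best first, ties broken by
    entity id.  An empty candidate set yields an empty list.
    """
    head = spec.head_entity
    if head is None or head not in kg.entity_id:
        mention = head if head is not None else spec.question_text
        hits = link_entity_fuzzy(mention, kg, threshold=link_threshold)
        if not hits:
            raise EntityNotFound(mention)
        head = hits[0][0]

    rel_id = None
    if spec.relation is not None and spec.relation in space.relation_id:
        rel_id = space.relation_id[spec.relation]
        r_vec = space.relation_embeddings[rel_id]
    else:
        if predictor is None:
            raise UnresolvedRelation(spec.relation or spec.question_text or "")
        text = spec.question_text if spec.question_text else (spec.relation or "")
        rel, r_vec = predict_relation_embedding(text, kg, space, predictor)
        rel_id = space.relation_id[rel]

    candidates = sorted(kg.n_hop_neighbors(head, spec.hop_limit, direction=direction),
                        key=lambda e: kg.entity_id[e])
    candidates = [c for c in candidates if c in space.entity_id]
    if not candidates:
        return []
    cids = np.array([space.entity_id[c] for c in candidates])
    hid = space.entity_id[head]
    scores = space.score_candidates(space.entity_embeddings[hid], r_vec, cids,
                                    relation_id=rel_id, h_id=hid)
    normalized = scores if space.score_polarity == "similarity" else -scores
    order = sorted(range(len(candidates)),
                   key=lambda i: (-normalized[i], kg.entity_id[candidates[i]]))
    out = []
    for i in order[: spec.top_k]:
        ent = candidates[i]
        out.append(ScoredCandidate(
            entity=ent,
            score=float(scores[i]),
            normalized_score=float(normalized[i]),
            ontology_label=space.ontology_label,
            numeric_values=kg.lateral_lookup(ent),
        ))
    return out


# ---------------------------------------------------------------------------
# Two-round numerical filtering


@dataclass
class NumericFilterResult:
    """Outcome of the two-round numeric filter."""

    answers: list[str]          # survivors of both rounds, by entity id order
    round1: list[str]           # entities whose predicted value passed
    no_data: list[str]          # round-1 survivors with no stored value


def _satisfies(v: float, operator: str, value: float, tau: float, slack: float = 0.0) -> bool:
    if operator == "smaller":
        return v < value + slack
    if operator == "larger":
        return v > value - slack
    return abs(v - value) <= tau + slack


def default_slack(
    kg: KnowledgeGraph, space: EmbeddingSpace, attribute: str
) -> float:
    """Round-1 slack: 2 sample standard deviations of the prediction residual
    ``v_hat - v`` over the attribute's stored triples (high-recall default)."""
    resid = [
        space.predict_attribute(e, a) - v
        for e, a, v, _ in kg.attribute_triples
        if a == attribute
    ]
    if len(resid) < 2:
        return 0.0
    return 2.0 * float(np.std(resid, ddof=1))


def numeric_filter_answer(
    attribute: str,
    operator: str,
    value: float,
    kg: KnowledgeGraph,
    space: EmbeddingSpace,
    tau: float | None = None,
    slack: float | None = None,
) -> NumericFilterResult:
    """Two-round numerical filtering over all entities of the graph.

    Round 1 keeps entities whose predicted value ``v_hat = e . l + b``
    satisfies the operator with slack (smaller: ``v_hat < value + slack``;
    larger: ``v_hat > value - slack``; close: ``|v_hat - value| <= tau +
    slack``).  Round 2 keeps round-1 survivors whose actual stored value
    satisfies the operator exactly; survivors without a stored value land in
    ``no_data``.  ``slack=inf`` disables round 1, making the pipeline an
    exact brute-force filter on stored values.
    """
    if operator not in OPERATORS:
        raise ValueError(f"unknown operator {operator!r}")
    if space.attribute_vectors is None:
        raise ValueError(f"{space.method} space carries no attribute parameters")
    if attribute not in space.attribute_id:
        raise KeyError(f"attribute {attribute!r} absent from the embedding space")
    tau_eff = tau if tau is not None else NumericQualifier("close", value).tau
    if slack is None:
        slack = default_slack(kg, space, attribute)

    aid = space.attribute_id[attribute]
    stored: dict[str, float] = {
        e: v for e, a, v, _ in kg.attribute_triples if a == attribute
    }
    round1: list[str] = []
    for ent in kg.entities:
        if ent not in space.entity_id:
            continue
        if np.isinf(slack):
            round1.append(ent)
            continue
        v_hat = float(space.entity_embeddings[space.entity_id[ent]]
                      @ space.attribute_vectors[aid] + space.attribute_bias[aid])
        if _satisfies(v_hat, operator, value, tau_eff, slack):
            round1.append(ent)

    answers, no_data = [], []
    for ent in round1:
        if ent not in stored:
            no_data.append(ent)
        elif _satisfies(stored[ent], operator, value, tau_eff):
            answers.append(ent)
    return NumericFilterResult(answers=answers, round1=round1, no_data=no_data)
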