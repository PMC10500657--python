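"""Knowledge-graph store: triples, numeric attribute triples, labels, and graph agents.

A :class:`KnowledgeGraph` holds relation triples ``(head, relation, tail)``
between entity IRIs, numeric attribute triples ``(entity, attribute, value,
unit)`` attaching literal values to entities, and a label table used for
entity linking.  Vocabularies (entities, relations, attributes) are indexed
with contiguous integer ids in first-seen order, which is the contract the
embedding trainer relies on.

Two serialization dialects are supported:

* **TSV** — a ``head<TAB>relation<TAB>tail`` section and an
  ``entity<TAB>attribute<TAB>value<TAB>unit`` section, each introduced by its
  header line; both may appear in one stream.
* **N-Triples subset** — ``<iri> <iri> <iri> .`` for relation triples and
  ``<iri> <iri> "number"^^xsd:double .`` for attribute triples.  Anything
  else (blank nodes, language tags, other datatypes) is rejected.

The module also provides the two graph primitives of the QA workflow: the
*subgraph agent* (:meth:`KnowledgeGraph.n_hop_neighbors`, candidate answers
within ``n`` hops of the head entity) and the *lateral lookup agent*
(:meth:`KnowledgeGraph.lateral_lookup`, the numeric literals attached to an
answer entity).
"""

from __future__ import annotations

import math
import re
from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

__all__ = [
    "Triple",
    "AttributeTriple",
    "EntityLabel",
    "KnowledgeGraph",
    "KGError",
    "ParseError",
    "EntityNotFound",
    "parse_triples",
    "write_triples",
    "COMPOSITE_SEPARATOR",
]

#: Reserved separator used by multihop derivation to join relation IRIs into
#: composite labels; forbidden in input relation IRIs (validated at parse time).
COMPOSITE_SEPARATOR = "|"

TSV_RELATION_HEADER = "head\trelation\ttail"
TSV_ATTRIBUTE_HEADER = "entity\tattribute\tvalue\tunit"
TSV_LABEL_HEADER = "iri\tlabel\ttype\taliases"


class KGError(Exception):
    """Base class for knowledge-graph errors."""


class ParseError(KGError):
    """A malformed input line; carries the 1-based line number and reason."""

    def __init__(self, lineno: int, reason: str):
        self.lineno = lineno
        self.reason = reason
        super().__init__(f"line {lineno}: {reason}")


class EntityNotFound(KGError):
    """An entity IRI absent from the graph's vocabulary."""


class Triple(NamedTuple):
    head: str
    relation: str
    tail: str


class AttributeTriple(NamedTuple):
    entity: str
    attribute: str
    value: float
    unit: str = ""


@dataclass(frozen=True)
class EntityLabel:
    """Display names for one entity: primary label, type tag, and aliases.

    Chemical formulas are carried as aliases; the fuzzy entity linker matches
    against the primary label and every alias.
    """

    label: str
    type_tag: str = ""
    aliases: tuple[str, ...] = ()

    def all_names(self) -> tuple[str, ...]:
        return (self.label, *self.aliases)


@dataclass
class KnowledgeGraph:
    """An indexed knowledge graph for one ontology."""

    ontology_label: str = "kg"
    entities: list[str] = field(default_factory=list)
    relations: list[str] = field(default_factory=list)
    attributes: list[str] = field(default_factory=list)
    relation_triples: set[Triple] = field(default_factory=set)
    attribute_triples: set[AttributeTriple] = field(default_factory=set)
    labels: dict[str, EntityLabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entity_id: dict[str, int] = {e: i for i, e in enumerate(self.entities)}
        self.relation_id: dict[str, int] = {r: i for i, r in enumerate(self.relations)}
        self.attribute_id: dict[str, int] = {a: i for i, a in enumerate(self.attributes)}
        self._adj_fwd: dict[str, list[str]] | None = None
        self._adj_bwd: dict[str, list[str]] | None = None

    # -- construction ------------------------------------------------------

    def _intern_entity(self, iri: str) -> int:
        if iri not in self.entity_id:
            self.entity_id[iri] = len(self.entities)
            self.entities.append(iri)
        return self.entity_id[iri]

    def _intern_relation(self, iri: str) -> int:
        if iri not in self.relation_id:
            self.relation_id[iri] = len(self.relations)
            self.relations.append(iri)
        return self.relation_id[iri]

    def _intern_attribute(self, iri: str) -> int:
        if iri not in self.attribute_id:
            self.attribute_id[iri] = len(self.attributes)
            self.attributes.append(iri)
        return self.attribute_id[iri]

    def add_triple(self, head: str, relation: str, tail: str) -> Triple:
        self._intern_entity(head)
        self._intern_relation(relation)
        self._intern_entity(tail)
        t = Triple(head, relation, tail)
        if t not in self.relation_triples:
            self.relation_triples.add(t)
            self._adj_fwd = self._adj_bwd = None
        return t

    def add_attribute(
        self, entity: str, attribute: str, value: float, unit: str = ""
    ) -> AttributeTriple:
        value = float(value)
        if not math.isfinite(value):
            raise KGError(f"attribute value for {entity!r}/{attribute!r} is not finite")
        self._intern_entity(entity)
        self._intern_attribute(attribute)
        t = AttributeTriple(entity, attribute, value, unit)
        self.attribute_triples.add(t)
        return t

    def set_label(
        self, iri: str, label: str, type_tag: str = "", aliases: Iterable[str] = ()
    ) -> None:
        self._intern_entity(iri)
        self.labels[iri] = EntityLabel(label, type_tag, tuple(aliases))

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        """Check index bijectivity/contiguity and triple vocabulary coverage."""
        for seq, index, kind in (
            (self.entities, self.entity_id, "entity"),
            (self.relations, self.relation_id, "relation"),
            (self.attributes, self.attribute_id, "attribute"),
        ):
            if len(seq) != len(set(seq)) or len(index) != len(seq):
                raise KGError(f"{kind} index is not a bijection")
            for i, item in enumerate(seq):
                if index[item] != i:
                    raise KGError(f"{kind} index is not contiguous from 0")
        for h, r, t in self.relation_triples:
            if h not in self.entity_id or t not in self.entity_id:
                raise KGError(f"triple ({h}, {r}, {t}) references unindexed entity")
            if r not in self.relation_id:
                raise KGError(f"triple ({h}, {r}, {t}) references unindexed relation")
        for e, a, v, _ in self.attribute_triples:
            if e not in self.entity_id:
                raise KGError(f"attribute triple of {e} references unindexed entity")
            if a not in self.attribute_id:
                raise KGError(f"attribute {a} is unindexed")
            if not math.isfinite(v):
                raise KGError(f"attribute value {v} of {e} is not finite")

    # -- graph agents ------------------------------------------------------

    def _adjacency(self) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
        if self._adj_fwd is None:
            fwd: dict[str, list[str]] = defaultdict(list)
            bwd: dict[str, list[str]] = defaultdict(list)
            for h, _, t in self.relation_triples:
                fwd[h].append(t)
                bwd[t].append(h)
            self._adj_fwd, self._adj_bwd = dict(fwd), dict(bwd)
        return self._adj_fwd, self._adj_bwd  # type: ignore[return-value]

    def n_hop_neighbors(self, head: str, n: int, direction: str = "forward") -> set[str]:
        """Subgraph agent: entities reachable from ``head`` by 1..n edges.

        ``direction`` is ``"forward"`` (follow edge direction) or ``"both"``
        (undirected traversal).  The head itself is excluded even if it lies
        on a cycle.
        """
        if head not in self.entity_id:
            raise EntityNotFound(head)
        if n < 1:
            raise ValueError("n must be >= 1")
        if direction not in ("forward", "both"):
            raise ValueError(f"unknown direction {direction!r}")
        fwd, bwd = self._adjacency()
        seen = {head}
        frontier = deque([(head, 0)])
        out: set[str] = set()
        while frontier:
            node, depth = frontier.popleft()
            if depth == n:
                continue
            neighbors = list(fwd.get(node, ()))
            if direction == "both":
                neighbors += bwd.get(node, ())
            for nxt in neighbors:
                if nxt not in seen:
                    seen.add(nxt)
                    out.add(nxt)
                    frontier.append((nxt, depth + 1))
        return out

    def lateral_lookup(self, entity: str) -> dict[str, tuple[float, str]]:
        """Lateral lookup agent: the numeric literals attached to one entity."""
        if entity not in self.entity_id:
            raise EntityNotFound(entity)
        return {
            a: (v, u) for e, a, v, u in self.attribute_triples if e == entity
        }

    # -- sizes -------------------------------------------------------------

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_relations(self) -> int:
        return len(self.relations)




# ---------------------------------------------------------------------------
# Parsing / serialization


_NT_RELATION = re.compile(r"^<([^<>\s]+)>\s+<([^<>\s]+)>\s+<([^<>\s]+)>\s*\.\s*$")
_NT_ATTRIBUTE = re.compile(
    r'^<([^<>\s]+)>\s+<([^<>\s]+)>\s+"([^"]*)"\^\^(?:xsd:double|'
    r"<http://www\.w3\.org/2001/XMLSchema#double>)\s*\.\s*$"
)


def parse_triples(
    text: str,
    format: str = "tsv",
    ontology_label: str = "kg",
    labels_text: str = "",
    allow_composite: bool = False,
) -> KnowledgeGraph:
    """Parse a character stream into a :class:`KnowledgeGraph`.

    ``format`` is ``"tsv"`` or ``"ntriples"``.  Duplicate triples collapse;
    vocabularies are built in first-seen order.  Malformed lines raise
    :class:`ParseError` with the line number; a non-numeric value in an
    attribute row is a parse error, and a bare literal in a relation position
    is rejected rather than silently treated as an attribute.  Relation IRIs
    containing the reserved composite separator ``"|"`` are rejected unless
    ``allow_composite`` is set (used when reading graphs already augmented
    with derived multihop relations).
    """
    kg = KnowledgeGraph(ontology_label=ontology_label)
    if format == "tsv":
        _parse_tsv(text, kg, allow_composite)
    elif format == "ntriples":
        _parse_ntriples(text, kg, allow_composite)
    else:
        raise ValueError(f"unknown format {format!r}")
    if labels_text:
        parse_labels(labels_text, kg)
    kg.validate()
    return kg


def _parse_tsv(text: str, kg: KnowledgeGraph, allow_composite: bool = False) -> None:
    section = "relations"
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line == TSV_RELATION_HEADER:
            section = "relations"
            continue
        if line == TSV_ATTRIBUTE_HEADER:
            section = "attributes"
            continue
        fields = line.split("\t")
        if section == "relations":
            if len(fields) != 3:
                raise ParseError(lineno, f"expected 3 tab-separated fields, got {len(fields)}")
            h, r, t = fields
            if not (h and r and t):
                raise ParseError(lineno, "empty field in relation triple")
            if _looks_numeric(t):
                raise ParseError(
                    lineno,
                    f"bare literal {t!r} in a relation tail position; numeric "
                    "values belong in the attribute section",
                )
            if COMPOSITE_SEPARATOR in r and not allow_composite:
                raise ParseError(
                    lineno,
                    f"relation IRI {r!r} contains the reserved separator "
                    f"{COMPOSITE_SEPARATOR!r}",
                )
            kg.add_triple(h, r, t)
        else:
            if len(fields) != 4:
                raise ParseError(lineno, f"expected 4 tab-separated fields, got {len(fields)}")
            e, a, v, u = fields
            if not (e and a):
                raise ParseError(lineno, "empty field in attribute triple")
            try:
                value = float(v)
            except ValueError:
                raise ParseError(lineno, f"non-numeric attribute value {v!r}") from None
            if not math.isfinite(value):
                raise ParseError(lineno, f"non-finite attribute value {v!r}")
            kg.add_attribute(e, a, value, u)


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _parse_ntriples(text: str, kg: KnowledgeGraph, allow_composite: bool = False) -> None:
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _NT_RELATION.match(line)
        if m:
            if COMPOSITE_SEPARATOR in m.group(2) and not allow_composite:
                raise ParseError(lineno, f"relation IRI {m.group(2)!r} contains "
                                 f"the reserved separator {COMPOSITE_SEPARATOR!r}")
            kg.add_triple(*m.groups())
            continue
        m = _NT_ATTRIBUTE.match(line)
        if m:
            e, a, v = m.groups()
            try:
                value = float(v)
            except ValueError:
                raise ParseError(lineno, f"non-numeric attribute value {v!r}") from None
            kg.add_attribute(e, a, value)
            continue
        raise ParseError(lineno, f"not in the accepted N-Triples subset: {line!r}")


def parse_labels(text: str, kg: KnowledgeGraph) -> None:
    """Parse the labels TSV dialect (``iri<TAB>label<TAB>type<TAB>aliases``)."""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line == TSV_LABEL_HEADER:
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(lineno, f"expected 4 tab-separated fields, got {len(fields)}")
        iri, label, type_tag, aliases = fields
        if not iri or not label:
            raise ParseError(lineno, "empty iri or label")
        kg.set_label(iri, label, type_tag, [a for a in aliases.split("|") if a])


def write_triples(kg: KnowledgeGraph, format: str = "tsv") -> str:
    """Serialize a graph deterministically (sorted by head, relation, tail ids)."""
    rel_key = lambda t: (kg.entity_id[t.head], kg.relation_id[t.relation], kg.entity_id[t.tail])
    attr_key = lambda t: (kg.entity_id[t.entity], kg.attribute_id[t.attribute], t.value, t.unit)
    rels = sorted(kg.relation_triples, key=rel_key)
    attrs = sorted(kg.attribute_triples, key=attr_key)
    if format == "tsv":
        lines = [TSV_RELATION_HEADER]
        lines += [f"{h}\t{r}\t{t}" for h, r, t in rels]
        if attrs:
            lines.append(TSV_ATTRIBUTE_HEADER)
            lines += [f"{e}\t{a}\t{v!r}\t{u}" for e, a, v, u in attrs]
        return "\n".join(lines) + "\n"
    if format == "ntriples":
        lines = [f"<{h}> <{r}> <{t}> ." for h, r, t in rels]
        lines += [f'<{e}> <{a}> "{v!r}"^^xsd:double .' for e, a, v, _ in attrs]
        return "\n".join(lines) + ("\n" if lines else "")
    raise ValueError(f"unknown format {format!r}")


def write_labels(kg: KnowledgeGraph) -> str:
    lines = [TSV_LABEL_HEADER]
    for iri in sorted(kg.labels, key=lambda i: kg.entity_id[i]):
        lab = kg.labels[iri]
        lines.append(f"{iri}\t{lab.label}\t{lab.type_tag}\t{'|'.join(lab.aliases)}")
    return "\n".join(lines) + "\n"
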