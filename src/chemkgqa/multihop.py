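"""Implicit multihop relation derivation.

Deep ontologies put a property several hops away from the entity it belongs
to (e.g. species -> calculation -> result -> numeric value), which makes a
one-hop embedding query miss it.  This module derives the implicit composite
relations ahead of training: it enumerates the relation-type paths of length
2..max_hops realized by simple entity paths, and materializes one new triple
(path start, composite label, path end) per realizing path.  Training on the
augmented graph then answers a deep question as a one-hop question over the
composite relation.

Composite labels join relation IRIs with ``"|"`` (reserved at parse time),
with a ``"^"`` prefix marking an inverse step when inverse traversal is
enabled.  Paths are simple (no repeated entities), so cyclic graphs do not
blow up and no derived self-loops arise from 2-cycles.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .kg import COMPOSITE_SEPARATOR, KnowledgeGraph, Triple

__all__ = ["DerivedRelation", "enumerate_relation_paths", "derive_implicit_triples",
           "augment_with_implicit_triples", "composite_label"]


@dataclass(frozen=True)
class DerivedRelation:
    """A composite relation: an ordered path of (relation IRI, inverse flag)."""

    path: tuple[tuple[str, bool], ...]

    def __post_init__(self) -> None:
        if len(self.path) < 2:
            raise ValueError("a derived relation needs at least 2 hops")

    @property
    def composite_label(self) -> str:
        return composite_label(self.path)


def composite_label(path: tuple[tuple[str, bool], ...]) -> str:
    return COMPOSITE_SEPARATOR.join(("^" if inv else "") + rel for rel, inv in path)


def _edges(kg: KnowledgeGraph, allow_inverse: bool):
    """Adjacency as node -> list of (neighbor, relation, inverse flag).

    Composite relations already present in the graph are excluded from the
    path alphabet, which makes derivation idempotent on augmented graphs.
    """
    adj: dict[str, list[tuple[str, str, bool]]] = defaultdict(list)
    for h, r, t in kg.relation_triples:
        if COMPOSITE_SEPARATOR in r:
            continue
        adj[h].append((t, r, False))
        if allow_inverse:
            adj[t].append((h, r, True))
    for lst in adj.values():
        lst.sort()
    return adj


def _simple_paths(kg: KnowledgeGraph, max_hops: int, allow_inverse: bool):
    """Yield (start, relation path, end) for every simple path of length 2..max_hops."""
    adj = _edges(kg, allow_inverse)
    for start in kg.entities:
        stack = [(start, (), {start})]
        while stack:
            node, rpath, visited = stack.pop()
            if len(rpath) == max_hops:
                continue
            for nxt, rel, inv in adj.get(node, ()):
                if nxt in visited:
                    continue
                new_path = rpath + ((rel, inv),)
                if len(new_path) >= 2:
                    yield start, new_path, nxt
                stack.append((nxt, new_path, visited | {nxt}))


def enumerate_relation_paths(
    kg: KnowledgeGraph,
    max_hops: int = 3,
    min_support: int = 1,
    allow_inverse: bool = False,
) -> list[DerivedRelation]:
    """Relation-type paths of length 2..max_hops with enough instance support.

    Support is the number of distinct simple entity paths realizing the
    relation path.  Results are deterministically ordered (path length, then
    lexicographic).
    """
    if max_hops < 2:
        raise ValueError("max_hops must be >= 2")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    support: dict[tuple[tuple[str, bool], ...], int] = defaultdict(int)
    for _, rpath, _ in _simple_paths(kg, max_hops, allow_inverse):
        support[rpath] += 1
    kept = [p for p, c in support.items() if c >= min_support]
    kept.sort(key=lambda p: (len(p), p))
    return [DerivedRelation(p) for p in kept]


def derive_implicit_triples(
    kg: KnowledgeGraph,
    relations: list[DerivedRelation],
    allow_inverse: bool | None = None,
) -> set[Triple]:
    """Materialize (start, composite label, end) triples for the given relations.

    One triple per realizing simple entity path, deduplicated.  The original
    graph is untouched.  A derived relation referencing an unknown relation
    IRI is an error.
    """
    for dr in relations:
        for rel, _ in dr.path:
            if rel not in kg.relation_id:
                raise KeyError(f"derived relation references unknown relation {rel!r}")
    if allow_inverse is None:
        allow_inverse = any(inv for dr in relations for _, inv in dr.path)
    wanted = {dr.path: dr.composite_label for dr in relations}
    max_hops = max((len(dr.path) for dr in relations), default=2)
    out: set[Triple] = set()
    for start, rpath, end in _simple_paths(kg, max_hops, allow_inverse):
        label = wanted.get(rpath)
        if label is not None:
            out.add(Triple(start, label, end))
    return out


def augment_with_implicit_triples(
    kg: KnowledgeGraph,
    max_hops: int = 3,
    min_support: int = 1,
    allow_inverse: bool = False,
) -> tuple[KnowledgeGraph, list[DerivedRelation], set[Triple]]:
    """Enumerate, derive, and return a new graph with the derived triples added."""
    relations = enumerate_relation_paths(kg, max_hops, min_support, allow_inverse)
    derived = derive_implicit_triples(kg, relations, allow_inverse)
    augmented = KnowledgeGraph(ontology_label=kg.ontology_label)
    for t in sorted(kg.relation_triples,
                    key=lambda t: (kg.entity_id[t.head], kg.relation_id[t.relation],
                                   kg.entity_id[t.tail])):
        augmented.add_triple(*t)
    for t in sorted(derived):
        augmented.add_triple(*t)
    for a in sorted(kg.attribute_triples):
        augmented.add_attribute(*a)
    for iri, lab in kg.labels.items():
        augmented.set_label(iri, lab.label, lab.type_tag, lab.aliases)
    return augmented, relations, derived
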