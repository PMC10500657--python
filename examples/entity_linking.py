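"""Fuzzy entity linking over labels, formulas, and aliases."""

from chemkgqa import KnowledgeGraph, link_entity_fuzzy, parse_numeric_operator

kg = KnowledgeGraph()
kg.add_triple("iri:benzene", "rel:weight", "iri:w")
kg.set_label("iri:benzene", "benzene", "species", ("C6H6", "benzol"))
kg.set_label("iri:w", "weight record", "record")

for mention in ("benzene", "benzen", "C6H6"):
    hits = link_entity_fuzzy(mention, kg, threshold=0.5)
    iri, sim, matched = hits[0]
    print(f"{mention!r:12} -> {iri} (similarity {sim:.2f}, via {matched!r}, "
          f"type {kg.labels[iri].type_tag!r})")

q = "what is the heat capacity of benzene at 100 K?"
print("numeric qualifier in question:", parse_numeric_operator(q))
# A misspelled mention still links through normalized edit distance; the
# regular-expression pass recognizes the qualifier "at 100 K" as a
# close-to filter with unit K.
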