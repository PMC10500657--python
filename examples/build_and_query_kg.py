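"""Build a small knowledge graph from TSV and query it with the graph agents."""

from chemkgqa import parse_triples

TEXT = """\
head	relation	tail
iri:benzene	rel:hasCalculation	iri:calc1
iri:calc1	rel:hasResult	iri:result1
iri:result1	rel:hasValue	iri:value1
entity	attribute	value	unit
iri:benzene	attr:molecularWeight	78.11	g/mol
"""

kg = parse_triples(TEXT)
print("entities:", kg.n_entities, "relations:", kg.n_relations)

# subgraph agent: candidate answers within n hops of the head entity
print("3-hop neighborhood of benzene:",
      sorted(kg.n_hop_neighbors("iri:benzene", 3, direction="forward")))

# lateral lookup agent: numeric literals attached to an entity
print("benzene literals:", kg.lateral_lookup("iri:benzene"))
# The neighborhood is where answers to questions about benzene are searched;
# the literals are what numerical questions filter on.
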