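"""Build a small predication graph from triples, write it out, read it back.

Predications are directed subject-PREDICATE-object assertions between
UMLS-style concepts; duplicates aggregate their sentence-support counts and
self-loops are dropped at load.
"""

import io

from hetepath import ConceptNode, KnowledgeGraph, Predication, read_triples, write_triples

graph = KnowledgeGraph()
for cui, name, semtype in [
    ("C9000001", "piroxicam-like drug", "PHSU"),
    ("C9000002", "second drug", "PHSU"),
    ("C9000011", "gene alpha", "GNGM"),
    ("C9000021", "movement disorder", "DSYN"),
]:
    graph.add_node(ConceptNode(cui, name, semtype))

graph.add_edge(Predication("C9000001", "AFFECTS", "C9000011", support_count=2))
graph.add_edge(Predication("C9000001", "AFFECTS", "C9000011", support_count=3))  # aggregates
graph.add_edge(Predication("C9000011", "ASSOCIATED_WITH", "C9000021"))
graph.add_edge(Predication("C9000002", "TREATS", "C9000021"))

buf = io.StringIO()
n_rows = write_triples(graph, buf)
print(f"serialized {n_rows} predications:")
print(buf.getvalue())

buf.seek(0)
again = read_triples(buf)
print("roundtrip identical:", again == graph)
print("degree of the disease node:", graph.degree("C9000021"))
# The AFFECTS edge shows support 5: the two duplicate assertions were merged.
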