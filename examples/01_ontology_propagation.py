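"""Propagate annotations under the true-path rule and compute information content.

Annotating a protein with a GO term implies annotation with every ancestor
term, so evaluation always works on the ancestor-closed sets. Information
content (-log2 of a term's training frequency) quantifies how specific, and
hence how informative, each term is.
"""

from gofunc import gen_annotations, gen_ontology, information_content

graph = gen_ontology(n_terms=30, seed=0)
annotations = gen_annotations(graph, n_proteins=20, seed=1)

protein, terms = next(iter(sorted(annotations.records.items())))
print(f"{protein} is annotated with {len(terms)} terms after propagation:")
print("  " + ", ".join(sorted(terms)))

ic = information_content(graph, annotations)
deepest = max(terms, key=lambda t: ic[t])
root = next(t for t in terms if graph.graph.out_degree(t) == 0)
print(f"most specific term {deepest}: {ic[deepest]:.2f} bits")
print(f"namespace root {root}: {ic[root]:.2f} bits")
print("high-IC terms are rare in training and dominate the Smin metric;")
print("roots carry almost none — every protein annotated in the namespace has them.")
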