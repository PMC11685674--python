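"""Build a leakage-free train/valid/test split from pairwise similarity hits.

Homologous proteins must not straddle the split, or the benchmark rewards
sequence memorization. Proteins are grouped into connected components of
the thresholded similarity graph and whole components are assigned to
train/valid/test at 81/9/10.
"""

from gofunc import assign_splits, gen_similarity_graph, similarity_components
from gofunc.dataset import SimilarityGraph, check_split_purity

proteins = [f"P{i:03d}" for i in range(200)]
hits, _ = gen_similarity_graph(proteins, n_components=80, seed=7)

groups = similarity_components(hits, evalue_max=1e-3, proteins=proteins)
split = assign_splits(groups, fractions=(0.81, 0.09, 0.10), seed=7)

frac = split.achieved_fractions()
print(f"{len(proteins)} proteins in {len(groups)} similarity components")
print(f"train/valid/test fractions: {frac[0]:.3f} / {frac[1]:.3f} / {frac[2]:.3f}")

sim = SimilarityGraph.from_hits(hits, proteins=proteins)
print(f"similarity edges crossing split boundaries: {check_split_purity(sim, split)}")
print("zero crossing edges means no test protein has a detectable homolog in training.")
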