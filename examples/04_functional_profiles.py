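"""Build binary and abundance-weighted functional profiles of a community.

For 16S data, each taxon's functions come from predictions on its reference
proteins; a sample's abundance-weighted value for function f is
A(f) = sum_i R(t_i) * I(f, t_i) — the total relative abundance of taxa
carrying f. A function carried by every taxon therefore gets A(f) = 1.
"""

from gofunc import (
    CommunitySpec,
    abundance_profile,
    binary_profile,
    gen_community,
    gen_ontology,
    wgs_binary_profile,
)

graph = gen_ontology(n_terms=60, seed=0)
spec = CommunitySpec(driver="function", effect_size=0.8, seed=4)
otu, taxon_functions, wgs_sets, labels = gen_community(spec, graph)

abundance = abundance_profile(otu, taxon_functions)
binary = binary_profile(otu, taxon_functions)
wgs = wgs_binary_profile(wgs_sets)

sample = otu.samples[0]
print(f"community: {len(otu.samples)} samples x {len(otu.taxa)} taxa, "
      f"{abundance.matrix.shape[1]} functions")
row = abundance.matrix.loc[sample]
top = row.sort_values(ascending=False).head(3)
print(f"top functions of sample {sample} (category {labels.label[sample]}):")
for f, a in top.items():
    print(f"  {f}: A(f) = {a:.3f}")
print(f"binary profile marks {int(binary.matrix.loc[sample].sum())} functions present")
print(f"WGS-style profile marks {int(wgs.matrix.loc[sample].sum())} functions present")
print("A(f) weighs each function by the abundance of its carriers, so dominant")
print("taxa shape the profile; the binary matrix only records presence.")
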