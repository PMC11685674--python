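"""Synthetic fixtures: toy ontologies, annotations, similarity hits, communities.

Everything the toolkit consumes can be generated here at desk scale, fully
deterministic under a seed: layered random GO DAGs with the three namespace
roots, true-path-consistent annotation tables, similarity graphs with known
connected components, and phenotype-labelled microbial communities whose
signal is planted either in taxon composition or in function content.

The community generator operationalizes the two regimes the profiling
analysis is meant to distinguish:

* ``driver="taxon"`` — each phenotype category consistently boosts a fixed
  block of taxa, while the taxon -> function map is label-independent and
  guild-balanced (every function carried by equally many taxa from each
  block, i.e. functional redundancy across blocks). Taxonomic profiles then
  separate the categories; functional profiles blur them.
* ``driver="function"`` — each category is tied to a guild of taxa that all
  carry that category's marker functions, but each sample boosts only a
  small random subset of its guild. Which taxa dominate varies within a
  category (weak taxonomic signal) while the summed abundance of the marker
  functions stays high (strong functional signal).
* ``driver="none"`` — labels are independent of the data entirely.

At effect size 0 every code path collapses to label-independent generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_eval import PhenotypeLabels
from .dataset import EXPERIMENTAL_EVIDENCE_CODES
from .ontology import AnnotationTable, OntologyGraph, propagate
from .profiles import AbundanceTable, SampleFunctionSets, TaxonFunctionMap

import networkx as nx

_NAMESPACE_ROOTS = {"MFO": "GO:0000001", "BPO": "GO:0000002", "CCO": "GO:0000003"}


def gen_ontology(n_terms: int, max_parents: int = 2, seed: int = 0) -> OntologyGraph:
    """Random layered DAG with one root per namespace; acyclic by construction.

    Terms beyond the three roots are assigned namespaces round-robin; each
    picks 1..max_parents parents among earlier terms of its namespace, so
    every non-root term reaches its namespace root.
    """
    if n_terms < 3:
        raise ValueError("need at least the three namespace roots")
    rng = np.random.default_rng(seed)
    graph = nx.DiGraph()
    namespace: dict[str, str] = {}
    by_ns: dict[str, list[str]] = {ns: [root] for ns, root in _NAMESPACE_ROOTS.items()}
    for ns, root in _NAMESPACE_ROOTS.items():
        graph.add_node(root)
        namespace[root] = ns
    ns_cycle = list(_NAMESPACE_ROOTS)
    for i in range(3, n_terms):
        term = f"GO:{i + 1:07d}"
        ns = ns_cycle[i % 3]
        pool = by_ns[ns]
        n_par = int(rng.integers(1, max_parents + 1))
        parents = rng.choice(len(pool), size=min(n_par, len(pool)), replace=False)
        graph.add_node(term)
        namespace[term] = ns
        for j in parents:
            graph.add_edge(term, pool[j], relation="is_a" if rng.random() < 0.8 else "part_of")
        pool.append(term)
    return OntologyGraph(graph=graph, namespace=namespace)


def gen_annotations(
    graph: OntologyGraph,
    n_proteins: int,
    depth_bias: float = 1.0,
    seed: int = 0,
    max_terms: int = 5,
) -> AnnotationTable:
    """Random propagated annotation table: 1..max_terms leaf-biased direct terms.

    Term sampling weight is (1 + depth)^depth_bias, so depth_bias 0 draws
    uniformly over non-root terms. Direct records get experimental evidence
    codes; the returned table is propagated (true-path consistent).
    """
    rng = np.random.default_rng(seed)
    roots = graph.root_terms
    candidates = sorted(graph.terms - roots)
    if not candidates:
        raise ValueError("ontology has no non-root terms to annotate with")
    depth = {}
    for t in candidates:
        anc = graph.ancestors(t)
        depth[t] = len(anc)
    w = np.array([(1.0 + depth[t]) ** depth_bias for t in candidates])
    w /= w.sum()
    codes = sorted(EXPERIMENTAL_EVIDENCE_CODES)
    rows = []
    for i in range(n_proteins):
        protein = f"P{i + 1:05d}"
        k = int(rng.integers(1, max_terms + 1))
        terms = rng.choice(len(candidates), size=min(k, len(candidates)), replace=False, p=w)
        for j in terms:
            rows.append((protein, candidates[j], codes[int(rng.integers(len(codes)))]))
    return propagate(graph, AnnotationTable.from_records(rows))


def gen_similarity_graph(
    proteins: list[str], n_components: int, seed: int = 0
) -> tuple[pd.DataFrame, list[set[str]]]:
    """Pairwise hits whose thresholded graph has exactly the returned components.

    Proteins are partitioned into ``n_components`` groups; within each group
    a random spanning chain of hits is emitted with e-values well below any
    sensible threshold. Returns (hits DataFrame, true components).
    """
    if n_components > len(proteins):
        raise ValueError("more components than proteins")
    rng = np.random.default_rng(seed)
    order = list(proteins)
    rng.shuffle(order)
    # one protein per component first, remainder distributed at random
    groups: list[list[str]] = [[order[i]] for i in range(n_components)]
    for p in order[n_components:]:
        groups[int(rng.integers(n_components))].append(p)
    rows = []
    for group in groups:
        for a, b in zip(group, group[1:]):
            ev = 10.0 ** float(rng.uniform(-50, -10))
            bs = float(rng.uniform(50, 500))
            rows.append((a, b, ev, bs))
    hits = pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])
    return hits, [set(g) for g in groups]


@dataclass
class CommunitySpec:
    """Parameters of a synthetic phenotype-labelled community."""

    n_samples_per_category: int = 10
    categories: tuple[str, ...] = ("A", "B", "C")
    n_taxa: int = 20
    n_functions: int = 30
    functions_per_taxon: int = 12
    n_markers: int = 4
    driver: str = "none"  # "taxon" | "function" | "none"
    effect_size: float = 0.8
    noise: float = 50.0  # Dirichlet concentration scale; higher = less noisy
    presence_floor: float = 0.02  # abundances below this are zeroed (detection limit)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.driver not in ("taxon", "function", "none"):
            raise ValueError(f"unknown driver {self.driver!r}")
        if not (0.0 <= self.effect_size <= 1.0):
            raise ValueError("effect size must be in [0, 1]")
        for name in ("n_samples_per_category", "n_taxa", "n_functions",
                     "functions_per_taxon", "n_markers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _function_pool(graph: OntologyGraph, n: int, rng: np.random.Generator) -> list[str]:
    candidates = sorted(graph.terms - graph.root_terms)
    if len(candidates) < n:
        raise ValueError(
            f"ontology has {len(candidates)} non-root terms, need {n}"
        )
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx)]


def gen_community(
    spec: CommunitySpec, graph: OntologyGraph
) -> tuple[AbundanceTable, TaxonFunctionMap, SampleFunctionSets, PhenotypeLabels]:
    """Generate one community: abundances, taxon->function map, WGS sets, labels."""
    rng = np.random.default_rng(spec.seed)
    k = len(spec.categories)
    taxa = [f"T{i + 1:03d}" for i in range(spec.n_taxa)]
    pool = _function_pool(graph, spec.n_functions, rng)

    # guilds: contiguous blocks of taxa, one per category
    guilds: dict[str, list[str]] = {}
    bounds = np.linspace(0, spec.n_taxa, k + 1).astype(int)
    for c, lo, hi in zip(spec.categories, bounds, bounds[1:]):
        guilds[c] = taxa[lo:hi]

    boost = 1.0 + 8.0 * spec.effect_size

    # --- taxon -> function map -------------------------------------------
    mapping: dict[str, set[str]] = {}
    markers: dict[str, list[str]] = {}
    if spec.driver == "function":
        # disjoint marker functions per category, carried by the whole guild
        flat = list(pool)
        need = spec.n_markers * k
        if need > len(flat):
            raise ValueError("n_markers * categories exceeds the function pool")
        for i, c in enumerate(spec.categories):
            markers[c] = flat[i * spec.n_markers : (i + 1) * spec.n_markers]
        marker_set = {f for fs in markers.values() for f in fs}
        background = [f for f in pool if f not in marker_set]
        for t in taxa:
            n_bg = min(spec.functions_per_taxon, len(background))
            idx = rng.choice(len(background), size=n_bg, replace=False)
            mapping[t] = {background[i] for i in idx}
        for c in spec.categories:
            for t in guilds[c]:
                mapping[t] |= set(markers[c])
    else:
        # label-independent, guild-balanced map (functional redundancy): each
        # function is carried by the same number of taxa from every guild, so
        # block-level composition shifts leave expected function abundance flat
        mapping = {t: set() for t in taxa}
        per_guild = max(
            1, round(spec.functions_per_taxon * spec.n_taxa / (spec.n_functions * k))
        )
        for f in pool:
            for c in spec.categories:
                guild = guilds[c]
                take = min(per_guild, len(guild))
                for i in rng.choice(len(guild), size=take, replace=False):
                    mapping[guild[i]].add(f)

    # --- abundances -------------------------------------------------------
    samples: list[str] = []
    labels: dict[str, str] = {}
    rows = []
    t_index = {t: i for i, t in enumerate(taxa)}
    for c in spec.categories:
        for r in range(spec.n_samples_per_category):
            s = f"{c}_{r + 1:02d}"
            samples.append(s)
            labels[s] = c
            mean = np.ones(spec.n_taxa)
            if spec.driver == "taxon":
                for t in guilds[c]:
                    mean[t_index[t]] *= boost
            elif spec.driver == "function":
                # one random guild taxon per sample: the carrier of the
                # category's marker functions varies, so taxonomic profiles
                # are inconsistent while marker-function abundance is stable
                guild = guilds[c]
                mean[t_index[guild[int(rng.integers(len(guild)))]]] *= boost
            mean /= mean.sum()
            alpha = spec.noise * mean * spec.n_taxa
            r_vec = rng.dirichlet(alpha)
            r_vec[r_vec < spec.presence_floor] = 0.0
            total = r_vec.sum()
            if total == 0:  # degenerate draw; keep the largest taxon
                r_vec[int(np.argmax(rng.dirichlet(alpha)))] = 1.0
            else:
                r_vec /= total
            rows.append(r_vec)

    otu = AbundanceTable(
        matrix=pd.DataFrame(np.array(rows), index=samples, columns=taxa)
    )

    # --- WGS-style per-sample function sets -------------------------------
    sets: dict[str, set[str]] = {}
    M = otu.matrix
    for s in samples:
        present = [t for t in taxa if M.loc[s, t] > 0]
        fs: set[str] = set()
        for t in present:
            fs |= mapping[t]
        sets[s] = fs

    fmap = TaxonFunctionMap(
        mapping=mapping,
        provenance=f"synthetic driver={spec.driver} effect={spec.effect_size}",
    )
    return (
        otu,
        fmap,
        SampleFunctionSets(sets=sets),
        PhenotypeLabels(label=labels, categories=list(spec.categories)),
    )
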