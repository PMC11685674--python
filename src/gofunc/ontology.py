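"""Gene Ontology graph handling: parsing, true-path propagation, information content.

The Gene Ontology (GO) is a directed acyclic graph of terms in three
namespaces (molecular function, biological process, cellular component).
Annotating a protein with a term implies every ancestor of that term along
``is_a`` and ``part_of`` edges (the true-path rule); all evaluation and
profiling downstream assumes annotation sets are closed under this rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relation types over which annotations propagate (DeepGO-family convention).
PROPAGATION_RELATIONS = ("is_a", "part_of")

#: Short namespace codes used throughout the package.
NAMESPACES = ("MFO", "BPO", "CCO")

_OBO_NAMESPACE_CODES = {
    "molecular_function": "MFO",
    "biological_process": "BPO",
    "cellular_component": "CCO",
}


class OntologyError(ValueError):
    """Raised for malformed ontologies or unknown terms."""


@dataclass
class OntologyGraph:
    """A GO DAG restricted to is_a/part_of edges.

    ``graph`` stores one directed edge per (child, parent) pair, pointing from
    child to parent, with a ``relation`` attribute. ``namespace`` maps each
    non-obsolete term to one of MFO/BPO/CCO. ``alt_ids`` maps secondary IDs to
    their primary term.
    """

    graph: nx.DiGraph
    namespace: dict[str, str]
    obsolete: set[str] = field(default_factory=set)
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise OntologyError("ontology graph contains a cycle")

    @property
    def terms(self) -> set[str]:
        """Non-obsolete term IDs."""
        return set(self.graph.nodes)

    @property
    def roots(self) -> dict[str, str]:
        """Map namespace code -> root term (no parents within the graph)."""
        out: dict[str, str] = {}
        for t in self.graph.nodes:
            if self.graph.out_degree(t) == 0:
                ns = self.namespace.get(t)
                if ns is not None:
                    out[ns] = t
        return out

    @property
    def root_terms(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def resolve(self, term: str) -> str:
        """Resolve an alt_id to its primary term ID (identity otherwise)."""
        return self.alt_ids.get(term, term)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` via parent links, excluding itself."""
        if term not in self.graph:
            raise OntologyError(f"unknown term: {term}")
        # edges point child -> parent, so graph-descendants are GO-ancestors
        return set(nx.descendants(self.graph, term))

    def descendants(self, term: str) -> set[str]:
        """All terms whose annotation implies ``term``, excluding itself."""
        if term not in self.graph:
            raise OntologyError(f"unknown term: {term}")
        return set(nx.ancestors(self.graph, term))

    def restrict_namespace(self, ns: str) -> "OntologyGraph":
        """Subgraph containing only terms of namespace ``ns`` and edges within it."""
        if ns not in NAMESPACES:
            raise OntologyError(f"unknown namespace {ns!r}; expected one of {NAMESPACES}")
        keep = {t for t, n in self.namespace.items() if n == ns and t in self.graph}
        if not keep:
            logger.warning("namespace restriction to %s yields an empty graph", ns)
        sub = nx.DiGraph(self.graph.subgraph(keep))
        return OntologyGraph(
            graph=sub,
            namespace={t: ns for t in keep},
            obsolete=set(self.obsolete),
            alt_ids={a: p for a, p in self.alt_ids.items() if p in keep},
        )


def parse_obo(path: str) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    Only ``is_a`` and ``part_of`` edges are retained; obsolete terms are
    recorded but carry no edges; ``alt_id`` lines are collected so secondary
    IDs can be resolved to primaries.
    """
    try:
        multi = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise OntologyError(f"failed to parse OBO file {path}: {exc}") from exc

    graph = nx.DiGraph()
    namespace: dict[str, str] = {}
    obsolete: set[str] = set()
    alt_ids: dict[str, str] = {}

    for term, data in multi.nodes(data=True):
        if data.get("is_obsolete") == "true":
            obsolete.add(term)
            continue
        graph.add_node(term)
        ns = data.get("namespace")
        if ns in _OBO_NAMESPACE_CODES:
            namespace[term] = _OBO_NAMESPACE_CODES[ns]
        elif ns in NAMESPACES:
            namespace[term] = ns
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term

    for child, parent, relation in multi.edges(keys=True):
        if relation not in PROPAGATION_RELATIONS:
            continue
        if child in obsolete or parent in obsolete:
            continue
        if parent not in multi.nodes or not multi.nodes[parent]:
            raise OntologyError(f"term {child} references unknown parent {parent}")
        graph.add_edge(child, parent, relation=relation)

    return OntologyGraph(graph=graph, namespace=namespace, obsolete=obsolete, alt_ids=alt_ids)


@dataclass
class AnnotationTable:
    """Protein -> set of GO terms, optionally with per-record evidence codes.

    ``evidence`` keeps the code of each *directly* asserted (protein, term)
    record; terms added by propagation carry no evidence entry.
    """

    records: dict[str, set[str]]
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)
    propagated: bool = False

    @classmethod
    def from_records(cls, rows: Iterable[tuple[str, str, str]]) -> "AnnotationTable":
        """Build from (protein, term, evidence_code) rows."""
        records: dict[str, set[str]] = {}
        evidence: dict[tuple[str, str], str] = {}
        for protein, term, code in rows:
            records.setdefault(protein, set()).add(term)
            evidence[(protein, term)] = code
        return cls(records=records, evidence=evidence)

    @property
    def proteins(self) -> set[str]:
        return set(self.records)

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.records.values():
            out |= ts
        return out

    def __len__(self) -> int:
        return len(self.records)


def propagate(graph: OntologyGraph, table: AnnotationTable) -> AnnotationTable:
    """Close every protein's annotation set under the ancestor relation.

    Annotations to obsolete terms are dropped with a warning; alt_ids are
    resolved first. Idempotent: propagating a propagated table returns an
    equal table.
    """
    unknown: set[str] = set()
    anc_cache: dict[str, set[str]] = {}
    new_records: dict[str, set[str]] = {}
    dropped = 0
    for protein, terms in table.records.items():
        closed: set[str] = set()
        for t in terms:
            t = graph.resolve(t)
            if t in graph.obsolete:
                dropped += 1
                continue
            if t not in graph.graph:
                unknown.add(t)
                continue
            if t not in anc_cache:
                anc_cache[t] = graph.ancestors(t)
            closed.add(t)
            closed |= anc_cache[t]
        new_records[protein] = closed
    if unknown:
        raise OntologyError(
            "annotation terms absent from ontology: " + ", ".join(sorted(unknown))
        )
    if dropped:
        logger.warning("dropped %d annotations to obsolete terms", dropped)
    return AnnotationTable(records=new_records, evidence=dict(table.evidence), propagated=True)


@dataclass
class ICTable:
    """Per-term information content in bits."""

    ic: dict[str, float]
    n_proteins: int = 0

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def get(self, term: str, default: float | None = None) -> float | None:
        return self.ic.get(term, default)


def information_content(graph: OntologyGraph, training: AnnotationTable) -> ICTable:
    """Annotation-frequency information content from a propagated training set.

    ic(t) = -log2(count(t) / N) with count(t) the number of training proteins
    annotated with t after propagation and N the number of training proteins.
    Terms never seen in training get the smoothed ceiling -log2(1 / (N + 1)).
    Roots (annotated in every protein once sets are propagated within a
    namespace universe) get ic near 0 by construction.
    """
    if not training.propagated:
        raise ValueError("information_content requires a propagated AnnotationTable")
    if len(training) == 0:
        raise ValueError("empty training set")
    n = len(training)
    counts: dict[str, int] = {}
    for terms in training.records.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    ceiling = -math.log2(1.0 / (n + 1))
    ic = {t: ceiling for t in graph.graph.nodes}
    for t, c in counts.items():
        ic[t] = -math.log2(c / n)
    return ICTable(ic=ic, n_proteins=n)


def restrict_annotations(
    table: AnnotationTable, terms: set[str] | Mapping[str, object]
) -> AnnotationTable:
    """Keep only annotations to ``terms``; proteins left empty are dropped."""
    keep = set(terms)
    records = {}
    for protein, ts in table.records.items():
        kept = ts & keep
        if kept:
            records[protein] = kept
    evidence = {k: v for k, v in table.evidence.items() if k[1] in keep}
    return AnnotationTable(records=records, evidence=evidence, propagated=table.propagated)
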