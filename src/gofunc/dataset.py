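"""Dataset construction: evidence filtering and leakage-free splits.

Function-prediction benchmarks leak badly if homologous proteins end up on
both sides of a train/test split. The splitter here groups proteins into
connected components of a thresholded sequence-similarity graph (all-vs-all
DIAMOND/BLAST hits at e-value <= 0.001 by default) and assigns whole
components to train/validation/test at 81/9/10, so no similarity edge ever
crosses a split boundary. A time-based split selects proteins first
experimentally annotated between two annotation releases (no-knowledge
convention, per namespace).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .ontology import AnnotationTable, OntologyGraph

logger = logging.getLogger(__name__)

#: The 13 experimental / curated evidence codes defining ground truth.
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC",
     "HTP", "HDA", "HMP", "HGI", "HEP"}
)

#: Default split fractions: train / validation / test.
DEFAULT_FRACTIONS = (0.81, 0.09, 0.10)

DEFAULT_EVALUE = 1e-3

SPLIT_LABELS = ("train", "valid", "test")


def filter_experimental(
    records: Iterable[tuple[str, str, str]] | AnnotationTable,
    codes: frozenset[str] = EXPERIMENTAL_EVIDENCE_CODES,
) -> AnnotationTable:
    """Keep only annotations with an experimental evidence code.

    Proteins left with zero surviving annotations are dropped. Computational
    codes (e.g. IEA) and unknown codes are filtered out, the latter logged.
    """
    if isinstance(records, AnnotationTable):
        rows = [
            (p, t, records.evidence.get((p, t), ""))
            for p, terms in records.records.items()
            for t in terms
        ]
    else:
        rows = list(records)
    kept: list[tuple[str, str, str]] = []
    unknown: set[str] = set()
    known_non_experimental = {"IEA", "ISS", "ISO", "ISA", "ISM", "IGC", "IBA",
                              "IBD", "IKR", "IRD", "RCA", "NAS", "ND"}
    for p, t, code in rows:
        if code in codes:
            kept.append((p, t, code))
        elif code not in known_non_experimental:
            unknown.add(code)
    if unknown:
        logger.warning("dropped records with unrecognized evidence codes: %s",
                       ", ".join(sorted(unknown)))
    return AnnotationTable.from_records(kept)


@dataclass
class SimilarityGraph:
    """Undirected protein similarity graph from thresholded pairwise hits."""

    graph: nx.Graph
    evalue_max: float

    @classmethod
    def from_hits(
        cls,
        hits: pd.DataFrame,
        evalue_max: float = DEFAULT_EVALUE,
        proteins: Sequence[str] | None = None,
    ) -> "SimilarityGraph":
        """Build from an outfmt-6-style DataFrame (qseqid, sseqid, evalue, bitscore).

        Both hit directions are merged; the best (lowest) e-value and highest
        bit score are kept per pair; self-hits are ignored. ``proteins``
        optionally adds isolated nodes for proteins with no qualifying hit.
        """
        g = nx.Graph()
        if proteins is not None:
            g.add_nodes_from(proteins)
        for q, s, ev, bs in zip(
            hits["qseqid"], hits["sseqid"], hits["evalue"], hits["bitscore"]
        ):
            if q == s or ev > evalue_max:
                continue
            if g.has_edge(q, s):
                data = g.edges[q, s]
                data["evalue"] = min(data["evalue"], float(ev))
                data["bitscore"] = max(data["bitscore"], float(bs))
            else:
                g.add_edge(q, s, evalue=float(ev), bitscore=float(bs))
        return cls(graph=g, evalue_max=evalue_max)


def similarity_components(
    hits: pd.DataFrame,
    evalue_max: float = DEFAULT_EVALUE,
    proteins: Sequence[str] | None = None,
) -> list[set[str]]:
    """Connected components of the thresholded similarity graph.

    Proteins listed in ``proteins`` but hitting nothing form singleton
    groups. Components are returned sorted by size (largest first) then by
    smallest member, for determinism.
    """
    sim = SimilarityGraph.from_hits(hits, evalue_max=evalue_max, proteins=proteins)
    comps = [set(c) for c in nx.connected_components(sim.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


@dataclass
class SplitAssignment:
    """Protein -> split label plus the targets and seed that produced it."""

    label: dict[str, str]
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    seed: int = 0

    def proteins(self, split: str) -> set[str]:
        return {p for p, s in self.label.items() if s == split}

    def achieved_fractions(self) -> tuple[float, float, float]:
        n = len(self.label)
        return tuple(
            sum(1 for s in self.label.values() if s == lab) / n for lab in SPLIT_LABELS
        )  # type: ignore[return-value]


def assign_splits(
    groups: Sequence[set[str]] | Sequence[frozenset[str]],
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole similarity groups to train/valid/test.

    Groups are shuffled with ``seed``, then taken largest-first; each goes to
    the bin whose current fill is furthest below its target protein count.
    Deterministic given the seed; achieved fractions are within one group of
    the targets. A single group larger than the biggest target bin goes to
    train with a warning.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    groups = [frozenset(g) for g in groups]
    all_proteins = [p for g in groups for p in g]
    if len(set(all_proteins)) != len(all_proteins):
        raise ValueError("groups do not partition the protein set (overlap found)")
    n_total = len(all_proteins)

    rng = random.Random(seed)
    order = sorted(groups, key=lambda g: min(g) if g else "")
    rng.shuffle(order)
    # stable largest-first; ties keep the shuffled order
    order.sort(key=len, reverse=True)

    targets = [f * n_total for f in fractions]
    fill = [0, 0, 0]
    label: dict[str, str] = {}
    for group in order:
        if len(group) > max(targets):
            bin_idx = 0
            logger.warning(
                "group of size %d exceeds the largest target bin; assigned to train",
                len(group),
            )
        else:
            deficits = [targets[i] - fill[i] for i in range(3)]
            bin_idx = max(range(3), key=lambda i: deficits[i])
        for p in group:
            label[p] = SPLIT_LABELS[bin_idx]
        fill[bin_idx] += len(group)
    return SplitAssignment(label=label, fractions=fractions, seed=seed)


def time_based_split(
    old: AnnotationTable, new: AnnotationTable, graph: OntologyGraph, ns: str
) -> set[str]:
    """Proteins first experimentally annotated in ``ns`` between two releases.

    No-knowledge convention: a protein qualifies if it has zero annotations
    in namespace ``ns`` in the old release and at least one in the new one.
    Both tables should already be filtered to experimental evidence codes.
    """
    ns_terms = {t for t, n in graph.namespace.items() if n == ns}

    def has_ns(table: AnnotationTable, protein: str) -> bool:
        return bool(table.records.get(protein, set()) & ns_terms)

    return {
        p for p in new.records
        if has_ns(new, p) and not has_ns(old, p)
    }


def dataset_summary(
    table: AnnotationTable,
    split: SplitAssignment | None,
    graph: OntologyGraph,
) -> pd.DataFrame:
    """Per-namespace dataset summary: unique non-root GO terms and protein counts.

    Mirrors the usual benchmark-summary schema: one row per sub-ontology with
    the number of distinct annotated terms (after propagation, roots
    excluded), total proteins, and train/valid/test counts.
    """
    from .ontology import propagate

    prop = table if table.propagated else propagate(graph, table)
    roots = graph.root_terms
    rows = []
    for ns in ("MFO", "BPO", "CCO"):
        ns_terms = {t for t, n in graph.namespace.items() if n == ns} - roots
        proteins = [p for p, ts in prop.records.items() if ts & ns_terms]
        terms: set[str] = set()
        for p in proteins:
            terms |= prop.records[p] & ns_terms
        counts = {lab: 0 for lab in SPLIT_LABELS}
        if split is not None:
            for p in proteins:
                lab = split.label.get(p)
                if lab is not None:
                    counts[lab] += 1
        rows.append(
            {
                "namespace": ns,
                "go_terms": len(terms),
                "proteins": len(proteins),
                "train": counts["train"],
                "valid": counts["valid"],
                "test": counts["test"],
            }
        )
    return pd.DataFrame(rows).set_index("namespace")


def check_split_purity(sim: SimilarityGraph, split: SplitAssignment) -> int:
    """Number of similarity edges crossing split labels (0 means leak-free)."""
    crossing = 0
    for u, v in sim.graph.edges:
        lu, lv = split.label.get(u), split.label.get(v)
        if lu is not None and lv is not None and lu != lv:
            crossing += 1
    return crossing
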