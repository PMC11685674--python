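"""Per-sample functional profiles of microbial communities.

Two routes from sequencing data to a sample x function matrix:

* **16S amplicon**: an OTU table of per-sample relative taxon abundances is
  combined with a taxon -> function map (functions predicted on each taxon's
  reference proteins). The profile is either binary (function present in the
  sample iff some taxon with abundance > 0 carries it) or abundance-weighted:

      A(f) = sum_i R(t_i) * I(f, t_i)

  the summed relative abundance of all taxa in the sample carrying f.
* **WGS**: each sample's assembled proteins are annotated directly; the
  sample's function set is the union over its proteins, giving a binary
  matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ontology import OntologyGraph
from .predictors import ScoreTable

logger = logging.getLogger(__name__)

#: Default score cutoff for calling a predicted function present.
DEFAULT_SCORE_CUTOFF = 0.3

_REL_TOL = 1e-6


@dataclass
class AbundanceTable:
    """Sample x taxon relative abundances; rows renormalized to 1 if needed."""

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.matrix
        if (m.to_numpy() < 0).any():
            raise ValueError("negative abundances")
        sums = m.sum(axis=1)
        off = (sums - 1.0).abs() > _REL_TOL
        if off.any():
            logger.warning(
                "renormalizing %d sample rows whose abundances did not sum to 1",
                int(off.sum()),
            )
            self.matrix = m.div(sums, axis=0)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class TaxonFunctionMap:
    """Taxon -> set of GO terms, with provenance of how the calls were made."""

    mapping: dict[str, set[str]]
    provenance: str = ""
    ancestor_closed: bool = False

    def functions(self) -> set[str]:
        out: set[str] = set()
        for fs in self.mapping.values():
            out |= fs
        return out


@dataclass
class FunctionProfileMatrix:
    """Sample x function matrix, binary or abundance-weighted."""

    matrix: pd.DataFrame
    mode: str = "binary"  # "binary" | "abundance"

    def binarize(self) -> "FunctionProfileMatrix":
        return FunctionProfileMatrix(
            matrix=(self.matrix > 0).astype(float), mode="binary"
        )


@dataclass
class SampleFunctionSets:
    """Sample -> set of functions derived from that sample's predicted proteins."""

    sets: dict[str, set[str]]

    @classmethod
    def from_wgs_annotations(
        cls,
        annotations: pd.DataFrame,
        graph: OntologyGraph | None = None,
        cutoff: float = DEFAULT_SCORE_CUTOFF,
    ) -> "SampleFunctionSets":
        """Aggregate per-sample protein annotations (sample, protein, go_term, score).

        Terms scoring >= cutoff are kept, unioned over the sample's proteins,
        and ancestor-closed when an ontology is supplied.
        """
        sets: dict[str, set[str]] = {}
        kept = annotations[annotations["score"] >= cutoff]
        for sample, term in zip(kept["sample"], kept["go_term"]):
            sets.setdefault(str(sample), set()).add(term)
        for sample in annotations["sample"].unique():
            sets.setdefault(str(sample), set())
        if graph is not None:
            sets = {s: _close(ts, graph) for s, ts in sets.items()}
        return cls(sets=sets)


def _close(terms: set[str], graph: OntologyGraph) -> set[str]:
    closed = set()
    for t in terms:
        t = graph.resolve(t)
        if t in graph.graph:
            closed.add(t)
            closed |= graph.ancestors(t)
    return closed


def taxon_function_map_from_scores(
    per_taxon_predictions: dict[str, ScoreTable],
    graph: OntologyGraph,
    cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> TaxonFunctionMap:
    """Call each taxon's function set from its proteins' prediction scores.

    functions(taxon) = union over the taxon's proteins of terms scoring
    >= cutoff, ancestor-closed. Taxa with zero proteins get an empty set.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    mapping: dict[str, set[str]] = {}
    for taxon, table in per_taxon_predictions.items():
        passing: set[str] = set()
        if not table.scores:
            logger.warning("taxon %s has no proteins; empty function set", taxon)
        for row in table.scores.values():
            passing |= {t for t, s in row.items() if s >= cutoff}
        mapping[taxon] = _close(passing, graph)
    return TaxonFunctionMap(
        mapping=mapping,
        provenance=f"score_cutoff={cutoff}",
        ancestor_closed=True,
    )


def _function_columns(
    otu: AbundanceTable, fmap: TaxonFunctionMap
) -> tuple[list[str], np.ndarray]:
    """Indicator matrix I (taxon x function) aligned with the OTU columns."""
    covered = [t for t in otu.taxa if t in fmap.mapping]
    uncovered = set(otu.taxa) - set(covered)
    if uncovered:
        logger.warning(
            "%d taxa have no function map entry and contribute nothing", len(uncovered)
        )
    functions = sorted({f for t in covered for f in fmap.mapping[t]})
    f_idx = {f: j for j, f in enumerate(functions)}
    I = np.zeros((len(otu.taxa), len(functions)))
    for i, taxon in enumerate(otu.taxa):
        for f in fmap.mapping.get(taxon, ()):
            I[i, f_idx[f]] = 1.0
    return functions, I


def abundance_profile(
    otu: AbundanceTable, fmap: TaxonFunctionMap
) -> FunctionProfileMatrix:
    """Abundance-weighted profile: cell(s, f) = sum_i R(t_i) * I(f, t_i)."""
    functions, I = _function_columns(otu, fmap)
    A = otu.matrix.to_numpy() @ I
    return FunctionProfileMatrix(
        matrix=pd.DataFrame(A, index=otu.matrix.index, columns=functions),
        mode="abundance",
    )


def binary_profile(otu: AbundanceTable, fmap: TaxonFunctionMap) -> FunctionProfileMatrix:
    """Binary profile: cell(s, f) = 1 iff some taxon with R > 0 in s carries f."""
    functions, I = _function_columns(otu, fmap)
    present = (otu.matrix.to_numpy() > 0).astype(float) @ I
    return FunctionProfileMatrix(
        matrix=pd.DataFrame(
            (present > 0).astype(float), index=otu.matrix.index, columns=functions
        ),
        mode="binary",
    )


def wgs_binary_profile(sets: SampleFunctionSets) -> FunctionProfileMatrix:
    """Binary sample x function matrix from per-sample WGS function sets."""
    samples = sorted(sets.sets)
    functions = sorted({f for fs in sets.sets.values() for f in fs})
    M = np.zeros((len(samples), len(functions)))
    f_idx = {f: j for j, f in enumerate(functions)}
    for i, s in enumerate(samples):
        for f in sets.sets[s]:
            M[i, f_idx[f]] = 1.0
    return FunctionProfileMatrix(
        matrix=pd.DataFrame(M, index=samples, columns=functions), mode="binary"
    )
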