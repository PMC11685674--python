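"""Baseline GO-term predictors and the universal score-table interface.

Every predictor — the annotation-frequency naive baseline, bitscore-weighted
annotation transfer (DiamondScore), the reference MLP on precomputed
embeddings, or any external tool whose output is loaded from a TSV — emits a
:class:`ScoreTable`: protein x GO term scores in [0, 1]. Evaluation and
profiling consume only this interface, so external deep models plug in via
their prediction files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ontology import AnnotationTable, OntologyGraph

logger = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Sparse protein x GO-term score matrix with scores in [0, 1].

    ``scores`` maps each protein to its {term: score} row; proteins with no
    prediction are present with an empty row so downstream metrics count them
    as zero-recall proteins.
    """

    scores: dict[str, dict[str, float]]
    model_name: str = ""

    def __post_init__(self) -> None:
        for p, row in self.scores.items():
            for t, s in row.items():
                if not (0.0 <= s <= 1.0):
                    raise ValueError(
                        f"score out of [0,1] for ({p}, {t}): {s}"
                    )

    @property
    def proteins(self) -> set[str]:
        return set(self.scores)

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for row in self.scores.values():
            out |= set(row)
        return out

    def get(self, protein: str, term: str) -> float:
        return self.scores.get(protein, {}).get(term, 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p, t, s) for p, row in self.scores.items() for t, s in row.items()
        ]
        return pd.DataFrame(rows, columns=["protein", "go_term", "score"])


def load_score_table(path: str, model_name: str = "") -> ScoreTable:
    """Load a prediction TSV ``protein<TAB>go_term<TAB>score``.

    Duplicate (protein, term) rows keep the maximum score; a score outside
    [0, 1] is rejected naming the offending row.
    """
    scores: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: expected 3 columns, got {len(parts)}")
            p, t, raw = parts[0], parts[1], parts[2]
            s = float(raw)
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"{path}:{i}: score {s} outside [0,1]")
            row = scores.setdefault(p, {})
            row[t] = max(row.get(t, 0.0), s)
    return ScoreTable(scores=scores, model_name=model_name or path)


def write_score_table(table: ScoreTable, path: str) -> None:
    with open(path, "w") as fh:
        for p in sorted(table.scores):
            for t, s in sorted(table.scores[p].items()):
                fh.write(f"{p}\t{t}\t{s:.6g}\n")


@dataclass
class NaiveFrequencyModel:
    """Predicts each term with its training annotation frequency, for every protein."""

    frequencies: dict[str, float]
    n_training: int

    def predict(self, proteins: list[str]) -> ScoreTable:
        row = dict(self.frequencies)
        return ScoreTable(
            scores={p: dict(row) for p in proteins}, model_name="naive"
        )


def naive_fit(training: AnnotationTable) -> NaiveFrequencyModel:
    """Fit the naive baseline: p(t) = fraction of training proteins annotated with t.

    The training table must be propagated so frequencies respect the
    true-path rule (a parent's frequency is then >= each child's).
    """
    if len(training) == 0:
        raise ValueError("empty training set")
    if not training.propagated:
        raise ValueError("naive_fit requires a propagated training table")
    n = len(training)
    counts: dict[str, int] = {}
    for terms in training.records.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return NaiveFrequencyModel(
        frequencies={t: c / n for t, c in counts.items()}, n_training=n
    )


def naive_predict(model: NaiveFrequencyModel, proteins: list[str]) -> ScoreTable:
    return model.predict(proteins)


def diamond_score_predict(
    hits: pd.DataFrame,
    training: AnnotationTable,
    queries: list[str],
) -> ScoreTable:
    """Bitscore-weighted annotation transfer from similar training proteins.

    For query q with hits to training proteins s (bit scores b_s):

        score(q, t) = sum(b_s for s with t in annotations(s)) / sum(b_s)

    summed over all hits of q whose subject is in the training table. Queries
    without hits get an empty prediction row. Hits to proteins absent from
    the training table are ignored (logged).
    """
    by_query: dict[str, list[tuple[str, float]]] = {}
    missing: set[str] = set()
    for q, s, bs in zip(hits["qseqid"], hits["sseqid"], hits["bitscore"]):
        if q == s:
            continue
        if s not in training.records:
            missing.add(s)
            continue
        by_query.setdefault(q, []).append((s, float(bs)))
    if missing:
        logger.warning(
            "ignored hits to %d proteins absent from the training table", len(missing)
        )
    scores: dict[str, dict[str, float]] = {}
    for q in queries:
        row: dict[str, float] = {}
        qhits = by_query.get(q, [])
        total = sum(b for _, b in qhits)
        if total > 0:
            for s, b in qhits:
                for t in training.records[s]:
                    row[t] = row.get(t, 0.0) + b
            row = {t: v / total for t, v in row.items()}
        scores[q] = row
    return ScoreTable(scores=scores, model_name="diamond")


def hierarchy_normalize(table: ScoreTable, graph: OntologyGraph) -> ScoreTable:
    """Make scores consistent with the true-path rule.

    Each term's score becomes the max over the term and its stored
    descendants, so score(parent) >= score(child) afterwards. Idempotent.
    """
    import networkx as nx

    order = list(nx.topological_sort(graph.graph))  # children before parents
    parents = {t: list(graph.graph.successors(t)) for t in graph.graph.nodes}
    scores: dict[str, dict[str, float]] = {}
    for p, row in table.scores.items():
        new_row = dict(row)
        for t in order:
            s = new_row.get(t)
            if s is None:
                continue
            for parent in parents[t]:
                if new_row.get(parent, 0.0) < s:
                    new_row[parent] = s
        scores[p] = new_row
    return ScoreTable(scores=scores, model_name=table.model_name)


@dataclass
class EmbeddingTable:
    """Fixed-length numeric vectors per protein (precomputed, e.g. by a PLM)."""

    vectors: dict[str, np.ndarray]
    dimension: int = 0

    def __post_init__(self) -> None:
        dims = {v.shape[0] for v in self.vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
        if dims:
            self.dimension = dims.pop()
        for p, v in self.vectors.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite embedding for {p}")

    @classmethod
    def read_tsv(cls, path: str) -> "EmbeddingTable":
        df = pd.read_csv(path, sep="\t", index_col=0, header=None)
        return cls(vectors={p: row.to_numpy(float) for p, row in df.iterrows()})


class MLPBaseline:
    """Reference multi-label MLP on protein embeddings.

    One hidden layer, sigmoid-style per-term outputs, trained with a fixed
    seed. A small desk-scale baseline exposing the same ScoreTable interface
    as every other predictor; no claim of fidelity to any particular deep
    architecture.
    """

    def __init__(self, hidden: int = 64, seed: int = 0, max_iter: int = 300):
        self.hidden = hidden
        self.seed = seed
        self.max_iter = max_iter
        self._clf = None
        self._terms: list[str] = []

    def fit(self, embeddings: EmbeddingTable, training: AnnotationTable) -> "MLPBaseline":
        from sklearn.neural_network import MLPClassifier

        proteins = [p for p in training.records if p in embeddings.vectors]
        if not proteins:
            raise ValueError("no training protein has an embedding")
        self._terms = sorted({t for p in proteins for t in training.records[p]})
        X = np.stack([embeddings.vectors[p] for p in proteins])
        Y = np.zeros((len(proteins), len(self._terms)), dtype=int)
        t_index = {t: j for j, t in enumerate(self._terms)}
        for i, p in enumerate(proteins):
            for t in training.records[p]:
                Y[i, t_index[t]] = 1
        # drop constant columns: MLPClassifier cannot learn single-class outputs
        self._constant = {}
        varying = []
        for j, t in enumerate(self._terms):
            col = Y[:, j]
            if col.min() == col.max():
                self._constant[t] = float(col[0])
            else:
                varying.append(j)
        self._varying_terms = [self._terms[j] for j in varying]
        if varying:
            self._clf = MLPClassifier(
                hidden_layer_sizes=(self.hidden,),
                random_state=self.seed,
                max_iter=self.max_iter,
            )
            self._clf.fit(X, Y[:, varying])
        return self

    def predict(self, embeddings: EmbeddingTable, proteins: list[str]) -> ScoreTable:
        if not self._terms:
            raise ValueError("model not fitted")
        scores: dict[str, dict[str, float]] = {}
        known = [p for p in proteins if p in embeddings.vectors]
        if known and self._clf is not None:
            X = np.stack([embeddings.vectors[p] for p in known])
            proba = self._clf.predict_proba(X)
            proba = np.asarray(proba, dtype=float)
        for p in proteins:
            row = {t: s for t, s in self._constant.items() if s > 0}
            scores[p] = row
        if known and self._clf is not None:
            for i, p in enumerate(known):
                for j, t in enumerate(self._varying_terms):
                    v = float(np.clip(proba[i, j], 0.0, 1.0))
                    if v > 0:
                        scores[p][t] = v
        return ScoreTable(scores=scores, model_name="mlp")
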