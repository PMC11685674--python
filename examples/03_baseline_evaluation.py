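"""Evaluate baseline predictors with the protein-centric metric suite.

The naive baseline predicts every term with its training frequency for
every protein, so its per-term ROC-AUC is exactly 0.5 — the floor any real
predictor must beat. Fmax/Smin/AUPR and the class-centric mean AUC are the
standard CAFA-style summary of a GO predictor.
"""

import numpy as np

from gofunc import (
    ScoreTable,
    evaluate,
    gen_annotations,
    gen_ontology,
    information_content,
    naive_fit,
)
from gofunc.ontology import AnnotationTable

graph = gen_ontology(n_terms=40, seed=2)
annotations = gen_annotations(graph, n_proteins=60, seed=3)
proteins = sorted(annotations.records)
train, test = proteins[:48], proteins[48:]
train_table = AnnotationTable(
    records={p: annotations.records[p] for p in train}, propagated=True
)
test_table = AnnotationTable(
    records={p: annotations.records[p] for p in test}, propagated=True
)
ic = information_content(graph, train_table)

naive = naive_fit(train_table).predict(test)
report = evaluate(naive, test_table, graph, ic)
print("naive baseline:")
print(f"  Fmax = {report.fmax:.3f} at threshold {report.optimal_threshold:.2f}")
print(f"  Smin = {report.smin:.3f} bits, AUPR = {report.aupr:.3f}, "
      f"mean AUC = {report.mean_auc:.3f}")

perfect = ScoreTable(
    scores={p: {t: 1.0 for t in test_table.records[p]} for p in test}
)
ideal = evaluate(perfect, test_table, graph, ic)
print("perfect predictor (truth as predictions):")
print(f"  Fmax = {ideal.fmax:.3f}, Smin = {ideal.smin:.3f}, "
      f"AUPR = {ideal.aupr:.3f}, mean AUC = {ideal.mean_auc:.3f}")
print("the naive AUC of exactly 0.5 reflects scores that ignore the protein;")
print("the perfect predictor pins Fmax/AUPR/AUC at 1 and Smin at 0.")
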