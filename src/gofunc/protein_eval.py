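"""Protein-centric evaluation of GO-term predictions: Fmax, Smin, AUPR, mean AUC.

The protocol follows the CAFA challenge conventions:

* **Fmax** — sweep a score threshold tau; at each tau, precision is averaged
  over proteins that predict at least one term at tau, recall over all
  evaluated proteins; Fmax is the best harmonic mean over the sweep.
* **Smin** — the minimum over tau of sqrt(ru^2 + mi^2), where remaining
  uncertainty ru is the mean summed information content of false-negative
  terms and misinformation mi that of false-positive terms.
* **AUPR** — micro-averaged precision-recall area over all
  (protein, term) pairs of the evaluation universe, trapezoidal integration
  over the distinct score cut points; pairs never predicted count as score 0.
* **mean AUC** — class-centric: per-term ROC-AUC over the evaluated
  proteins, averaged (unweighted) over terms with at least one positive and
  one negative protein.

Root terms are excluded from the evaluation universe; truth tables must be
propagated (true-path closed) first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .ontology import AnnotationTable, ICTable, OntologyGraph
from .predictors import ScoreTable

#: CAFA-style threshold grid: 0.01, 0.02, ..., 1.00.
DEFAULT_THRESHOLDS = np.round(np.arange(0.01, 1.001, 0.01), 2)


@dataclass
class EvaluationReport:
    """Bundle of the four protein-function metrics plus the threshold curve."""

    fmax: float
    optimal_threshold: float
    smin: float
    aupr: float
    mean_auc: float
    curve: list[tuple[float, float, float, float, float]] = field(default_factory=list)
    """Per-threshold (tau, precision, recall, remaining_uncertainty, misinformation)."""


def _universe(
    preds: ScoreTable,
    truth: AnnotationTable,
    graph: OntologyGraph | None,
    terms: set[str] | None,
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Dense score matrix S and truth matrix Y over the evaluation universe.

    Proteins: truth proteins with >= 1 (non-root) annotation. Terms: the
    given universe, or the union of truth and predicted terms; roots are
    excluded when an ontology is supplied.
    """
    roots = graph.root_terms if graph is not None else set()
    if terms is None:
        term_set = (truth.terms | preds.terms) - roots
    else:
        term_set = set(terms) - roots
    term_list = sorted(term_set)
    t_idx = {t: j for j, t in enumerate(term_list)}
    proteins = sorted(
        p for p, ts in truth.records.items() if ts & term_set
    )
    if not proteins:
        raise ValueError("empty truth: no protein has an annotation in the universe")
    S = np.zeros((len(proteins), len(term_list)))
    Y = np.zeros((len(proteins), len(term_list)), dtype=bool)
    for i, p in enumerate(proteins):
        for t in truth.records[p]:
            j = t_idx.get(t)
            if j is not None:
                Y[i, j] = True
        for t, s in preds.scores.get(p, {}).items():
            j = t_idx.get(t)
            if j is not None:
                S[i, j] = s
    return proteins, term_list, S, Y


def _thresholds(S: np.ndarray, exact: bool) -> np.ndarray:
    if not exact:
        return DEFAULT_THRESHOLDS
    vals = np.unique(S[S > 0])
    return vals if vals.size else np.array([1.0])


def _sweep(S: np.ndarray, Y: np.ndarray, taus: np.ndarray, ic_vec: np.ndarray | None):
    """Per-threshold precision/recall and (if ic given) ru/mi, vectorized per tau."""
    n = S.shape[0]
    rows = []
    for tau in taus:
        P = S >= tau
        tp = (P & Y).sum(axis=1)
        fp = (P & ~Y).sum(axis=1)
        fn = (~P & Y).sum(axis=1)
        covered = (tp + fp) > 0
        prec = float(np.mean(tp[covered] / (tp[covered] + fp[covered]))) if covered.any() else 0.0
        rec = float(np.mean(tp / np.maximum(tp + fn, 1)))
        if ic_vec is None:
            ru = mi = 0.0
        else:
            ru = float(((~P & Y) @ ic_vec).sum() / n)
            mi = float(((P & ~Y) @ ic_vec).sum() / n)
        rows.append((float(tau), prec, rec, ru, mi, covered.any()))
    return rows


def fmax(
    preds: ScoreTable,
    truth: AnnotationTable,
    graph: OntologyGraph | None = None,
    terms: set[str] | None = None,
    exact: bool = False,
) -> tuple[float, float]:
    """Protein-centric Fmax and the threshold attaining it (ties -> smallest tau)."""
    _, _, S, Y = _universe(preds, truth, graph, terms)
    best_f, best_tau = 0.0, float(_thresholds(S, exact)[0])
    for tau, prec, rec, _, _, any_cov in _sweep(S, Y, _thresholds(S, exact), None):
        if not any_cov or prec + rec == 0:
            continue
        f = 2 * prec * rec / (prec + rec)
        if f > best_f + 1e-12:
            best_f, best_tau = f, tau
    return best_f, best_tau


def smin(
    preds: ScoreTable,
    truth: AnnotationTable,
    ic: ICTable,
    graph: OntologyGraph | None = None,
    terms: set[str] | None = None,
    exact: bool = False,
) -> float:
    """Minimum semantic distance sqrt(ru^2 + mi^2) over the threshold sweep."""
    _, term_list, S, Y = _universe(preds, truth, graph, terms)
    missing = [t for t in term_list if ic.get(t) is None]
    if missing:
        raise ValueError("missing information content for terms: " + ", ".join(missing[:5]))
    ic_vec = np.array([ic[t] for t in term_list])
    best = np.inf
    for _, _, _, ru, mi, _ in _sweep(S, Y, _thresholds(S, exact), ic_vec):
        best = min(best, float(np.hypot(ru, mi)))
    return best


def aupr(
    preds: ScoreTable,
    truth: AnnotationTable,
    graph: OntologyGraph | None = None,
    terms: set[str] | None = None,
) -> float:
    """Micro-averaged PR area over all (protein, term) pairs of the universe."""
    _, _, S, Y = _universe(preds, truth, graph, terms)
    s = S.ravel()
    y = Y.ravel()
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("no positive (protein, term) pair in the truth")
    taus = np.unique(s[s > 0])[::-1]
    recs, precs = [], []
    for tau in taus:
        pred = s >= tau
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        precs.append(tp / (tp + fp) if tp + fp else 1.0)
        recs.append(tp / n_pos)
    if not recs:
        return 0.0
    # anchor the curve at recall 0 with the highest-threshold precision
    recs = [0.0] + recs
    precs = [precs[0]] + precs
    return float(np.trapezoid(precs, recs))


def term_centric_auc(
    preds: ScoreTable,
    truth: AnnotationTable,
    graph: OntologyGraph | None = None,
    terms: set[str] | None = None,
) -> float:
    """Unweighted mean per-term ROC-AUC over terms with >=1 positive and negative."""
    _, _, S, Y = _universe(preds, truth, graph, terms)
    aucs = []
    for j in range(Y.shape[1]):
        y = Y[:, j]
        if y.all() or not y.any():
            continue
        aucs.append(roc_auc_score(y, S[:, j]))
    if not aucs:
        raise ValueError("no term with both positive and negative proteins")
    return float(np.mean(aucs))


def evaluate(
    preds: ScoreTable,
    truth: AnnotationTable,
    graph: OntologyGraph | None = None,
    ic: ICTable | None = None,
    terms: set[str] | None = None,
    exact: bool = False,
) -> EvaluationReport:
    """Compute Fmax, Smin, AUPR and mean per-term AUC with the threshold curve."""
    _, term_list, S, Y = _universe(preds, truth, graph, terms)
    ic_vec = None
    if ic is not None:
        missing = [t for t in term_list if ic.get(t) is None]
        if missing:
            raise ValueError(
                "missing information content for terms: " + ", ".join(missing[:5])
            )
        ic_vec = np.array([ic[t] for t in term_list])
    taus = _thresholds(S, exact)
    rows = _sweep(S, Y, taus, ic_vec)
    best_f, best_tau = 0.0, float(taus[0])
    best_s = np.inf
    curve = []
    for tau, prec, rec, ru, mi, any_cov in rows:
        curve.append((tau, prec, rec, ru, mi))
        if any_cov and prec + rec > 0:
            f = 2 * prec * rec / (prec + rec)
            if f > best_f + 1e-12:
                best_f, best_tau = f, tau
        if ic_vec is not None:
            best_s = min(best_s, float(np.hypot(ru, mi)))
    return EvaluationReport(
        fmax=best_f,
        optimal_threshold=best_tau,
        smin=float(best_s) if ic_vec is not None else float("nan"),
        aupr=aupr(preds, truth, graph, terms),
        mean_auc=term_centric_auc(preds, truth, graph, terms),
        curve=curve,
    )
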