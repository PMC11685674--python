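"""Brute-force reference implementations, independent of the package's code paths.

Everything here is plain-Python loops over dicts: transitive closure by DFS,
threshold sweeps enumerating every distinct score, trapezoids by hand. Used
to freeze expected values and to cross-check the vectorized implementations.
"""

import math


def closure_dfs(edges, term):
    """Ancestors of ``term`` by explicit DFS over a child->parents dict."""
    seen = set()
    stack = [term]
    while stack:
        t = stack.pop()
        for p in edges.get(t, ()):
            if p not in seen:
                seen.add(p)
                stack.append(p)
    return seen


def _pred_at(preds, protein, tau):
    return {t for t, s in preds.get(protein, {}).items() if s >= tau}


def _distinct_thresholds(preds):
    vals = sorted({s for row in preds.values() for s in row.values() if s > 0})
    return vals or [1.0]


def oracle_fmax(preds, truth):
    """Max F1 over every distinct score threshold (protein-centric averaging)."""
    best = 0.0
    for tau in _distinct_thresholds(preds):
        precs, recs = [], []
        for p, true_terms in truth.items():
            pred_terms = _pred_at(preds, p, tau)
            tp = len(pred_terms & true_terms)
            if pred_terms:
                precs.append(tp / len(pred_terms))
            recs.append(tp / len(true_terms))
        if not precs:
            continue
        prec = sum(precs) / len(precs)
        rec = sum(recs) / len(recs)
        if prec + rec > 0:
            best = max(best, 2 * prec * rec / (prec + rec))
    return best


def oracle_smin(preds, truth, ic):
    """Min sqrt(ru^2 + mi^2) over every distinct score threshold."""
    universe = set()
    for ts in truth.values():
        universe |= ts
    for row in preds.values():
        universe |= set(row)
    best = math.inf
    n = len(truth)
    for tau in _distinct_thresholds(preds):
        ru = mi = 0.0
        for p, true_terms in truth.items():
            pred_terms = _pred_at(preds, p, tau) & universe
            for t in true_terms - pred_terms:
                ru += ic[t]
            for t in pred_terms - true_terms:
                mi += ic[t]
        ru /= n
        mi /= n
        best = min(best, math.hypot(ru, mi))
    return best


def oracle_aupr(preds, truth):
    """Micro PR area by pair enumeration and hand trapezoid, anchored at recall 0."""
    terms = set()
    for ts in truth.values():
        terms |= ts
    for row in preds.values():
        terms |= set(row)
    pairs = []
    for p in truth:
        for t in sorted(terms):
            s = preds.get(p, {}).get(t, 0.0)
            pairs.append((s, t in truth[p]))
    n_pos = sum(1 for _, y in pairs if y)
    taus = sorted({s for s, _ in pairs if s > 0}, reverse=True)
    points = []
    for tau in taus:
        tp = sum(1 for s, y in pairs if s >= tau and y)
        fp = sum(1 for s, y in pairs if s >= tau and not y)
        points.append((tp / n_pos, tp / (tp + fp) if tp + fp else 1.0))
    if not points:
        return 0.0
    points = [(0.0, points[0][1])] + points
    area = 0.0
    for (r0, p0), (r1, p1) in zip(points, points[1:]):
        area += (r1 - r0) * (p0 + p1) / 2.0
    return area


def oracle_purity(assignments, labels):
    """Classical clustering purity: majority-category fraction, by counting."""
    clusters = {}
    for s, c in assignments.items():
        clusters.setdefault(c, []).append(labels[s])
    total = sum(
        max(members.count(cat) for cat in set(members))
        for members in clusters.values()
    )
    return total / len(assignments)


def random_instance(rng, n_proteins, n_terms, density=0.4):
    """A random (preds, truth) pair over small protein/term universes."""
    proteins = [f"p{i}" for i in range(n_proteins)]
    terms = [f"t{j}" for j in range(n_terms)]
    truth, preds = {}, {}
    for p in proteins:
        k = int(rng.integers(1, max(2, n_terms // 2)))
        idx = rng.choice(n_terms, size=k, replace=False)
        truth[p] = {terms[j] for j in idx}
        row = {}
        for t in terms:
            if rng.random() < density:
                row[t] = float(rng.integers(1, 100)) / 100.0
        preds[p] = row
    return preds, truth
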