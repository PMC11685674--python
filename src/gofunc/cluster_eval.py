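"""Phenotype-recovery evaluation of community profiles.

Whether a profile type (taxonomic OTU abundances, binary or
abundance-weighted functional profiles, external pathway matrices) captures
a phenotype is judged by unsupervised recovery: PCA-reduce the sample
matrix, k-means cluster with k equal to the number of phenotype categories,
and score the clustering against the known labels with weighted average
clustering purity (WACP),

    WACP = (1/N) * sum_clusters max_category w_j * n_ij

with n_ij the count of category-j samples in cluster i and uniform weights
w_j = 1 by default (classical size-weighted purity). Optional category
weights correct for class imbalance; they are normalized to mean 1 so the
uniform case reproduces classical purity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

#: Fraction of total variance the PCA reduction retains by default.
DEFAULT_VARIANCE_TARGET = 0.9

DEFAULT_N_RESTARTS = 10


@dataclass
class PhenotypeLabels:
    """Sample -> phenotype category, with a stable category ordering."""

    label: dict[str, str]
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.categories:
            self.categories = sorted(set(self.label.values()))

    @classmethod
    def from_metadata(cls, metadata: pd.DataFrame, phenotype: str) -> "PhenotypeLabels":
        col = metadata[phenotype].dropna()
        return cls(label={str(s): str(v) for s, v in col.items()})

    @property
    def k(self) -> int:
        return len(self.categories)

    def vector(self, samples: Sequence[str]) -> list[str]:
        return [self.label[s] for s in samples]


@dataclass
class ClusteringReport:
    """Cluster assignments, contingency audit table and the WACP value."""

    assignments: dict[str, int]
    contingency: pd.DataFrame  # clusters x categories counts n_ij
    wacp: float
    class_weights: dict[str, float]
    seed: int = 0

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.contingency.sum(axis=1)

    @property
    def n(self) -> int:
        return int(self.contingency.to_numpy().sum())


def pca_reduce(
    matrix: pd.DataFrame,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
    n_components: int | None = None,
) -> pd.DataFrame:
    """Project samples onto leading principal components.

    Keeps the smallest number of components whose cumulative explained
    variance reaches ``variance_target`` (or exactly ``n_components`` when
    given). Component signs are fixed by making each component's
    largest-magnitude loading positive, so the reduction is deterministic.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant matrix has no variance to reduce")
    max_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=max_comp, svd_solver="full")
    Z = pca.fit_transform(X)
    if n_components is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_components = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        n_components = min(n_components, max_comp)
    n_components = min(n_components, max_comp)
    comps = pca.components_[:n_components]
    signs = np.sign(comps[np.arange(n_components), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    Z = Z[:, :n_components] * signs
    return pd.DataFrame(
        Z, index=matrix.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )


def kmeans_assign(
    points: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
) -> dict[str, int]:
    """Seeded k-means (k-means++ init, ``n_restarts`` restarts, best inertia)."""
    n = points.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if k < 2:
        raise ValueError("k must be >= 2")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(np.asarray(points, dtype=float))
    return {str(s): int(c) + 1 for s, c in zip(points.index, labels)}


def wacp(
    assignments: Mapping[str, int],
    labels: PhenotypeLabels,
    weights: Mapping[str, float] | None = None,
    seed: int = 0,
) -> ClusteringReport:
    """Weighted average clustering purity of a clustering against phenotype labels.

    With uniform (default) weights this is classical purity: the fraction of
    samples belonging to their cluster's majority category. Custom category
    weights are normalized to mean 1.
    """
    if set(assignments) != set(labels.label):
        raise ValueError("assignments and labels cover different sample sets")
    cats = labels.categories
    if weights is None:
        w = {c: 1.0 for c in cats}
    else:
        missing = set(cats) - set(weights)
        if missing:
            raise ValueError(f"weights missing for categories: {sorted(missing)}")
        mean_w = np.mean([weights[c] for c in cats])
        w = {c: weights[c] / mean_w for c in cats}

    clusters = sorted(set(assignments.values()))
    table = pd.DataFrame(0, index=clusters, columns=cats, dtype=int)
    for s, c in assignments.items():
        table.loc[c, labels.label[s]] += 1
    n = len(assignments)
    weighted = table.to_numpy(dtype=float) * np.array([w[c] for c in cats])
    value = float(weighted.max(axis=1).sum() / n)
    return ClusteringReport(
        assignments=dict(assignments),
        contingency=table,
        wacp=value,
        class_weights=w,
        seed=seed,
    )


def cluster_purity(
    matrix: pd.DataFrame,
    labels: PhenotypeLabels,
    seed: int = 0,
    k: int | None = None,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
    weights: Mapping[str, float] | None = None,
) -> ClusteringReport:
    """One profile matrix end to end: PCA -> k-means (k = #categories) -> WACP."""
    k = k or labels.k
    samples = [str(s) for s in matrix.index]
    missing = set(samples) - set(labels.label)
    if missing:
        raise ValueError(f"samples without phenotype label: {sorted(missing)[:5]}")
    sub_labels = PhenotypeLabels(
        label={s: labels.label[s] for s in samples}, categories=labels.categories
    )
    reduced = pca_reduce(matrix, variance_target=variance_target)
    assignments = kmeans_assign(reduced, k=k, seed=seed)
    return wacp(assignments, sub_labels, weights=weights, seed=seed)


def compare_profiles(
    profiles: Mapping[str, pd.DataFrame],
    labels: PhenotypeLabels,
    k: int | None = None,
    seeds: Sequence[int] = (0,),
    variance_target: float = DEFAULT_VARIANCE_TARGET,
) -> pd.DataFrame:
    """WACP of each named profile matrix across seeds.

    Runs pca_reduce -> kmeans_assign -> wacp per (matrix, seed). Returns a
    table with one row per profile type: per-seed WACP columns and their
    mean — the layout used to compare taxonomic against functional profiles.
    """
    sample_sets = {name: tuple(m.index) for name, m in profiles.items()}
    first = next(iter(sample_sets.values()))
    if any(set(s) != set(first) for s in sample_sets.values()):
        raise ValueError("profile matrices do not share one sample set")
    rows = {}
    for name, matrix in profiles.items():
        vals = [
            cluster_purity(
                matrix, labels, seed=seed, k=k, variance_target=variance_target
            ).wacp
            for seed in seeds
        ]
        rows[name] = {f"seed_{s}": v for s, v in zip(seeds, vals)}
        rows[name]["mean_wacp"] = float(np.mean(vals))
    out = pd.DataFrame(rows).T
    out.index.name = "profile"
    return out
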