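"""PCA, sample-correlation clustering, and tissue-vs-species agreement scores.

These are the computational cores of the study's figures: PCA of the
transposed log-expression matrix (samples as observations, centered and
scaled, invariant genes removed), and a heatmap-style hierarchical
clustering of the sample-correlation matrix (by default: complete linkage
on Euclidean distances between the *rows of the correlation matrix* — the
behavior of the standard heatmap tool when handed a correlation matrix —
with 1 - correlation and plain data-space Euclidean available as
robustness variants).

Because the published claims ("clusters by species", "clusters by tissue")
are visual, two quantitative agreement scores make them testable:

* ARI — adjusted Rand index between a dendrogram cut and a label set;
* nearest-neighbor purity — the fraction of samples whose most-correlated
  other sample carries the same label.
"""

from __future__ import annotations


import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "ClusterResult",
    "pca",
    "correlation_matrix",
    "hcluster",
    "nn_purity",
    "label_agreement",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_fraction: np.ndarray
    dropped_invariant_genes: list[str]


def pca(m: ExpressionMatrix, center: bool = True, scale: bool = True) -> PCAResult:
    """PCA of the transposed matrix (samples as observations).

    Genes with sample variance exactly 0 are removed first.  With
    ``scale=True`` each gene is divided by its (n-1)-denominator standard
    deviation.  Component signs are fixed so that each loading vector's
    largest-magnitude entry is positive, making outputs reproducible.
    """
    if m.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = m.values.to_numpy(dtype=float).T  # samples x genes
    genes = np.asarray(m.values.index)
    var = X.var(axis=0)
    invariant = var == 0
    dropped = [str(g) for g in genes[invariant]]
    X = X[:, ~invariant]
    genes = genes[~invariant]
    if center:
        X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=1)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    frac = s**2 / np.sum(s**2)
    scores = U * s
    loadings = Vt.T
    # sign convention: largest-|.| loading entry positive per component
    for c in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[i, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.values.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=genes, columns=comp_names),
        variance_fraction=frac,
        dropped_invariant_genes=dropped,
    )


def correlation_matrix(m: ExpressionMatrix, method: str = "pearson") -> pd.DataFrame:
    """Sample-by-sample correlation over genes (Pearson or Spearman).

    Spearman is Pearson on within-column ranks with average ranks at
    ties.  A zero-variance sample yields NaN correlations and a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    corr = m.values.corr(method=method)
    bad = corr.columns[corr.isna().any()].tolist()
    if bad:
        logger.warning("zero-variance samples, correlations undefined: %s", bad)
    return corr


@dataclass
class ClusterResult:
    samples: list[str]
    merges: list[tuple[int, int, float, int]]  # (id_a, id_b, height, new_size)
    distance: str
    linkage: str
    correlation: pd.DataFrame | None = None

    def cut(self, k: int) -> dict[str, int]:
        """Partition into k clusters (state after n - k merges), labels 0..k-1
        numbered by first member appearance."""
        n = len(self.samples)
        if not (1 <= k <= n):
            raise ValueError(f"k must be in [1, {n}]")
        parent = {i: i for i in range(n)}
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        next_id = n
        for a, b, _, _ in self.merges[: n - k]:
            members[next_id] = members.pop(a) + members.pop(b)
            next_id += 1
        clusters = sorted(members.values(), key=min)
        out = {}
        for label, mem in enumerate(clusters):
            for i in mem:
                out[self.samples[i]] = label
        return out

    def to_newick(self) -> str:
        n = len(self.samples)
        node = {i: self.samples[i] for i in range(n)}
        next_id = n
        h = ""
        for a, b, height, _ in self.merges:
            node[next_id] = f"({node.pop(a)},{node.pop(b)}):{height:.6g}"
            next_id += 1
        (root,) = node.values()
        return root + ";"


def _pairwise_euclidean(points: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import squareform, pdist

    return squareform(pdist(points, metric="euclidean"))


def hcluster(
    m: ExpressionMatrix | pd.DataFrame,
    dist_source: str = "corr_rows_euclidean",
    linkage: str = "complete",
    corr_method: str = "pearson",
) -> ClusterResult:
    """Agglomerative clustering of samples with deterministic tie-breaking.

    ``dist_source`` selects the sample-space distances:

    * ``corr_rows_euclidean`` — Euclidean distance between rows of the
      sample-correlation matrix (the heatmap default);
    * ``one_minus_corr`` — 1 - correlation directly as distance;
    * ``data_euclidean`` — Euclidean distance between sample columns of
      the data matrix.

    Ties in the minimum inter-cluster distance are broken by merging the
    lexicographically smallest (id_a, id_b) pair, where cluster ids are
    original sample indices 0..n-1 followed by merge order n, n+1, ...
    """
    if linkage not in ("complete", "average", "ward"):
        raise ValueError(f"unknown linkage {linkage!r}")
    corr = None
    if dist_source == "corr_rows_euclidean":
        corr = correlation_matrix(m, corr_method) if isinstance(m, ExpressionMatrix) else m
        D = _pairwise_euclidean(corr.to_numpy())
        samples = list(corr.columns)
    elif dist_source == "one_minus_corr":
        corr = correlation_matrix(m, corr_method) if isinstance(m, ExpressionMatrix) else m
        D = 1.0 - corr.to_numpy()
        np.fill_diagonal(D, 0.0)
        samples = list(corr.columns)
    elif dist_source == "data_euclidean":
        values = m.values if isinstance(m, ExpressionMatrix) else m
        D = _pairwise_euclidean(values.to_numpy().T)
        samples = list(values.columns)
    else:
        raise ValueError(f"unknown dist_source {dist_source!r}")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances (zero-variance sample?)")

    n = len(samples)
    dist: dict[tuple[int, int], float] = {}
    size = {i: 1 for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), height = best
        new_size = size[a] + size[b]
        merges.append((a, b, height, new_size))
        active.discard(a)
        active.discard(b)
        d_ab = dist.pop((a, b))
        new_dists = {}
        for w in active:
            d_aw = dist.pop(tuple(sorted((a, w))))
            d_bw = dist.pop(tuple(sorted((b, w))))
            if linkage == "complete":
                d = max(d_aw, d_bw)
            elif linkage == "average":
                d = (size[a] * d_aw + size[b] * d_bw) / new_size
            else:  # ward (Lance-Williams on distances, as in standard packages)
                sw = size[w]
                d = np.sqrt(
                    ((sw + size[a]) * d_aw**2 + (sw + size[b]) * d_bw**2 - sw * d_ab**2)
                    / (new_size + sw)
                )
            new_dists[(w, next_id)] = float(d)
        size[next_id] = new_size
        active.add(next_id)
        dist.update(new_dists)
        next_id += 1
    return ClusterResult(
        samples=samples,
        merges=merges,
        distance=dist_source,
        linkage=linkage,
        correlation=corr,
    )


def nn_purity(corr: pd.DataFrame, labels: Mapping[str, str]) -> float:
    """Fraction of samples whose most-correlated other sample shares the label."""
    samples = list(corr.columns)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    hits = 0
    C = corr.to_numpy().copy()
    np.fill_diagonal(C, -np.inf)
    for j, s in enumerate(samples):
        nn = samples[int(np.argmax(C[:, j]))]
        hits += labels[s] == labels[nn]
    return hits / len(samples)


def label_agreement(
    partition: Mapping[str, int],
    labels: Mapping[str, str],
    corr: pd.DataFrame | None = None,
) -> dict:
    """ARI between a partition and a label set, plus (if a correlation
    matrix is given) nearest-neighbor purity of the labels."""
    samples = sorted(partition)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if set(samples) != set(labels):
        raise ValueError("partition and labels cover different samples")
    ari = float(
        adjusted_rand_score(
            [str(labels[s]) for s in samples], [partition[s] for s in samples]
        )
    )
    out = {"ari": ari}
    if corr is not None:
        out["nn_purity"] = nn_purity(corr, labels)
    return out
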