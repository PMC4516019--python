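"""End-to-end pipeline drivers used by the analysis scripts and tests.

``normalize_counts`` runs the batch-aware preprocessing stack on a raw
count matrix; ``tissue_species_metrics`` scores a log-expression matrix
for how strongly samples group by species vs by tissue (nearest-neighbor
purities, dendrogram-cut ARIs, and the standardized species separation in
the first two principal components).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import correlation_matrix, hcluster, label_agreement, nn_purity, pca
from .matrix import ExpressionMatrix
from .normalize import (
    depth_normalize,
    filter_counts,
    gc_normalize_within_sample,
    log_transform,
    tmm_factors,
)
from .study_design import SampleRecord

__all__ = ["normalize_counts", "tissue_species_metrics"]


def normalize_counts(
    m: ExpressionMatrix,
    gc: pd.Series,
    mito_genes: Sequence[str] = (),
    filter_fraction: float = 0.3,
    gc_method: str = "full_quantile",
    num_bins: int = 10,
) -> ExpressionMatrix:
    """Low-expression filter, mitochondrial removal, within-sample GC
    normalization, TMM + depth normalization, log2(x + 1)."""
    fr = filter_counts(m, fraction=filter_fraction, mito_genes=list(mito_genes))
    gc_norm = gc_normalize_within_sample(fr.kept, gc, method=gc_method, num_bins=num_bins)
    factors = tmm_factors(gc_norm)
    depth = depth_normalize(gc_norm, factors)
    return log_transform(depth)


def tissue_species_metrics(
    m: ExpressionMatrix, samples: Sequence[SampleRecord]
) -> dict:
    """Tissue-vs-species clustering scores of a log-expression matrix.

    Returns nearest-neighbor purity per factor, ARI of the complete-linkage
    dendrogram cut at 2 (vs species) and at the number of tissues (vs
    tissue), and the absolute standardized difference of species mean
    scores on PC1 and PC2.
    """
    species = {s.sample_id: s.species for s in samples}
    tissue = {s.sample_id: s.tissue for s in samples}
    n_tissues = len(set(tissue.values()))

    corr = correlation_matrix(m, "pearson")
    tree = hcluster(corr, dist_source="corr_rows_euclidean", linkage="complete")
    cut2 = tree.cut(2)
    cutk = tree.cut(n_tissues)

    p = pca(m)
    scores = p.scores[["PC1", "PC2"]]
    groups = pd.Series(species).reindex(scores.index)
    sep = {}
    for pc in ("PC1", "PC2"):
        by = scores[pc].groupby(groups)
        pooled_sd = float(scores[pc].std(ddof=1))
        means = by.mean()
        sep[pc] = float(abs(means.iloc[0] - means.iloc[1]) / pooled_sd)

    return {
        "nn_purity_species": nn_purity(corr, species),
        "nn_purity_tissue": nn_purity(corr, tissue),
        "ari_species_cut2": label_agreement(cut2, species)["ari"],
        "ari_tissue_cut2": label_agreement(cut2, tissue)["ari"],
        "ari_species_cutk": label_agreement(cutk, species)["ari"],
        "ari_tissue_cutk": label_agreement(cutk, tissue)["ari"],
        "pc12_species_separation": float(np.hypot(sep["PC1"], sep["PC2"])),
        "variance_fraction": p.variance_fraction[:6].tolist(),
    }
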