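#!/usr/bin/env python
"""Score tissue-vs-species clustering before and after batch correction.

For both the normalized and the batch-corrected matrix: sample-correlation
heatmap clustering (complete linkage on Euclidean distances between
correlation-matrix rows), PCA of the transposed matrix, nearest-neighbor
purities and dendrogram-cut ARIs.  Writes results/clustering.json, the
dendrograms as Newick, PCA scores, and (if matplotlib is available) a
heatmap + PC1/PC2 scatter per matrix.
"""

import json
from pathlib import Path

import pandas as pd

from confoundr.cluster import correlation_matrix, hcluster, pca
from confoundr.matrix import ExpressionMatrix
from confoundr.pipeline import tissue_species_metrics
from confoundr.study_design import SampleRecord

ROOT = Path(__file__).resolve().parent.parent / "results"


def plots(name, corr, scores, meta):
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import seaborn as sns
    except ImportError:
        return
    fig = sns.clustermap(corr, cmap="vlag", center=corr.to_numpy().mean())
    fig.savefig(ROOT / f"heatmap_{name}.png", dpi=120)
    plt.close("all")
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"human": "tab:red", "mouse": "tab:blue"}
    for sp in ("human", "mouse"):
        sel = meta.species == sp
        ax.scatter(
            scores.loc[meta.sample_id[sel], "PC1"],
            scores.loc[meta.sample_id[sel], "PC2"],
            c=colors[sp],
            label=sp,
            s=18,
        )
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(ROOT / f"pca_{name}.png", dpi=120)
    plt.close("all")


def main() -> None:
    meta = pd.read_csv(ROOT / "sim" / "samples.tsv", sep="\t")
    samples = [
        SampleRecord(r.sample_id, r.species, r.tissue) for r in meta.itertuples()
    ]
    out = {}
    for name, path in (("uncorrected", "normalized.tsv"), ("corrected", "corrected.tsv")):
        m = ExpressionMatrix.from_tsv(ROOT / path)
        metrics = tissue_species_metrics(m, samples)
        out[name] = metrics
        corr = correlation_matrix(m, "pearson")
        tree = hcluster(corr, dist_source="corr_rows_euclidean", linkage="complete")
        (ROOT / f"dendrogram_{name}.nwk").write_text(tree.to_newick() + "\n")
        p = pca(m)
        p.scores.iloc[:, :6].to_csv(ROOT / f"pca_scores_{name}.tsv", sep="\t")
        plots(name, corr, p.scores, meta)
        print(
            f"{name:11s}: species NN purity {metrics['nn_purity_species']:.2f}, "
            f"tissue NN purity {metrics['nn_purity_tissue']:.2f}, "
            f"cut-2 ARI(species) {metrics['ari_species_cut2']:.2f}, "
            f"cut-13 ARI(tissue) {metrics['ari_tissue_cutk']:.2f}"
        )
    (ROOT / "clustering.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {ROOT / 'clustering.json'} (+ dendrograms, PCA scores, figures)")


if __name__ == "__main__":
    main()
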