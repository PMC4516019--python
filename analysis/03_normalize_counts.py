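#!/usr/bin/env python
"""Run the preprocessing stack on the raw count matrix.

30% low-expression filter, removal of the 12 mitochondrial genes,
within-sample full-quantile GC normalization, TMM composition factors,
depth normalization against the original unfiltered column sums, and
log2(x + 1).  Writes results/normalized.tsv (+ provenance sidecar).
"""

from pathlib import Path

import pandas as pd

from confoundr.matrix import ExpressionMatrix
from confoundr.pipeline import normalize_counts

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    m = ExpressionMatrix.from_tsv(ROOT / "sim" / "counts.tsv")
    gc_df = pd.read_csv(ROOT / "sim" / "gc.tsv", sep="\t")
    gc = pd.Series(gc_df.gc_fraction.to_numpy(), index=gc_df.common_name.astype(str))
    mito = (ROOT / "sim" / "mito.txt").read_text().split()

    norm = normalize_counts(m, gc, mito)
    norm.to_tsv(ROOT / "normalized.tsv")

    steps = " -> ".join(p["step"] for p in norm.provenance)
    print(f"normalization chain: {steps}")
    print(
        f"{m.shape[0]} genes -> {norm.shape[0]} after filtering "
        f"({m.shape[0] - norm.shape[0]} removed: 30% lowest + {len(mito)} mitochondrial)"
    )
    print(f"wrote {ROOT / 'normalized.tsv'}")


if __name__ == "__main__":
    main()
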