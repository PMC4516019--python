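"""Assembly of the ortholog expression matrix from per-sample quantification tables.

Quantifier output (featureCounts-style counts or Cufflinks-style FPKM)
identifies genes by their ENSEMBL gene identifier, while the ortholog table
uses common gene names.  The per-species GC table, which carries both
identifiers, provides the bridge.  Two real-world wrinkles are handled
explicitly:

* *retired identifiers* — gene ids dropped from ENSEMBL but still present
  in the annotation; their values are ignored;
* *duplicate common names* — several surviving gene ids sharing one common
  name; the id appearing first in the GC table wins.

The assembled matrix has one row per ortholog pair (ortholog-table order)
and one column per sample (metadata order).  A pair's row takes the human
gene's value in human columns and the mouse gene's value in mouse columns.
For raw counts the column sums of the quantifier's *full* output are
captured as the library-size proxy before any subsetting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .orthologs import OrthologTable
from .study_design import SampleRecord

logger = logging.getLogger(__name__)

__all__ = [
    "QuantTable",
    "read_featurecounts",
    "read_cufflinks_fpkm",
    "resolve_gene_ids",
    "assemble_matrix",
]


@dataclass
class QuantTable:
    """One sample's per-gene quantification (gene_id -> value)."""

    sample_id: str
    values: pd.Series  # index: gene_id
    value_kind: str  # raw_count | fpkm

    def __post_init__(self):
        if self.value_kind not in ("raw_count", "fpkm"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if (self.values < 0).any():
            raise ValueError(f"negative values in quant table for {self.sample_id}")


def read_featurecounts(path, sample_id: str | None = None) -> QuantTable:
    """Read a featureCounts output table (Geneid first column, counts last)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    values = pd.Series(
        df.iloc[:, -1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str)
    )
    return QuantTable(
        sample_id=sample_id or Path(path).stem, values=values, value_kind="raw_count"
    )


def read_cufflinks_fpkm(path, sample_id: str | None = None) -> QuantTable:
    """Read a Cufflinks genes.fpkm_tracking table (tracking_id + FPKM columns)."""
    df = pd.read_csv(path, sep="\t")
    values = pd.Series(
        df["FPKM"].to_numpy(dtype=float), index=df["tracking_id"].astype(str)
    )
    return QuantTable(
        sample_id=sample_id or Path(path).stem, values=values, value_kind="fpkm"
    )


def resolve_gene_ids(
    quant: QuantTable,
    gc_table: pd.DataFrame,
    retired_ids: set[str] | frozenset[str] = frozenset(),
) -> tuple[pd.Series, dict]:
    """Map a quant table from gene ids to common names.

    ``gc_table`` must have ``gene_id`` and ``common_name`` columns; its row
    order defines "first appearance" for duplicate common names.  Retired
    ids are dropped.  Quantified ids absent from the GC table are dropped
    with a logged count.  Returns (common_name -> value, stats).
    """
    stats = {"n_retired_dropped": 0, "n_unknown_dropped": 0, "n_name_collisions": 0}
    id_to_name: dict[str, str] = dict(
        zip(gc_table["gene_id"].astype(str), gc_table["common_name"].astype(str))
    )
    resolved: dict[str, float] = {}
    # iterate in GC-table order so first appearance of a common name wins
    quant_ids = set(quant.values.index)
    for gene_id in gc_table["gene_id"].astype(str):
        if gene_id not in quant_ids:
            continue
        if gene_id in retired_ids:
            stats["n_retired_dropped"] += 1
            continue
        name = id_to_name[gene_id]
        if name in resolved:
            stats["n_name_collisions"] += 1
            continue
        resolved[name] = float(quant.values[gene_id])
    unknown = quant_ids - set(id_to_name)
    stats["n_unknown_dropped"] = len(unknown)
    if unknown:
        logger.warning(
            "%s: %d quantified gene ids absent from the GC table were dropped",
            quant.sample_id,
            len(unknown),
        )
    return pd.Series(resolved), stats


def assemble_matrix(
    quants: Sequence[QuantTable],
    samples: Sequence[SampleRecord],
    orthologs: OrthologTable,
    human_gc: pd.DataFrame,
    mouse_gc: pd.DataFrame,
    retired_human: set[str] = frozenset(),
    retired_mouse: set[str] = frozenset(),
) -> ExpressionMatrix:
    """Build the ortholog-pairs x samples matrix.

    Rows are indexed by the *human* common name of each ortholog pair and
    follow ortholog-table order; columns follow the sample-metadata order.
    A gene missing from a sample's quant table contributes 0 (quantifiers
    emit explicit zero rows, so absence usually means identifier drift)
    and is warned about.
    """
    by_id = {q.sample_id: q for q in quants}
    if len(by_id) != len(quants):
        raise ValueError("duplicate sample_id among quant tables")
    kinds = {q.value_kind for q in quants}
    if len(kinds) != 1:
        raise ValueError(f"mixed value kinds among quant tables: {sorted(kinds)}")
    value_kind = kinds.pop()

    species_of = {s.sample_id: s.species for s in samples}
    missing = [s.sample_id for s in samples if s.sample_id not in by_id]
    if missing:
        raise ValueError(f"no quant table for samples: {missing}")

    human_names = orthologs.human_names()
    mouse_names = orthologs.mouse_names()
    mouse_to_human = dict(zip(mouse_names, human_names))

    columns = {}
    proxies = {}
    n_zero_filled = 0
    for s in samples:
        quant = by_id[s.sample_id]
        if s.species == "human":
            resolved, stats = resolve_gene_ids(quant, human_gc, retired_human)
            wanted = resolved.reindex(human_names)
        elif s.species == "mouse":
            resolved, stats = resolve_gene_ids(quant, mouse_gc, retired_mouse)
            resolved = resolved.rename(index=mouse_to_human)
            wanted = resolved.reindex(human_names)
        else:
            raise ValueError(f"unknown species {s.species!r} for {s.sample_id}")
        n_missing = int(wanted.isna().sum())
        if n_missing:
            n_zero_filled += n_missing
            logger.warning(
                "%s: %d ortholog genes missing from quant table, filled with 0",
                s.sample_id,
                n_missing,
            )
        columns[s.sample_id] = wanted.fillna(0.0).to_numpy()
        # proxy from the quantifier's FULL output, before ortholog subsetting
        proxies[s.sample_id] = float(quant.values.sum())

    values = pd.DataFrame(columns, index=pd.Index(human_names, name="gene"))
    values = values[[s.sample_id for s in samples]]
    proxy = (
        pd.Series(proxies) if value_kind == "raw_count" else None
    )
    return ExpressionMatrix(
        values=values,
        value_kind=value_kind,
        library_size_proxy=proxy,
        provenance=[
            {
                "step": "assemble_matrix",
                "n_pairs": len(orthologs.pairs),
                "n_samples": len(samples),
                "n_zero_filled": n_zero_filled,
                "ortholog_parse_mode": orthologs.parse_mode,
            }
        ],
    )
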