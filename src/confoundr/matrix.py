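"""The genes x samples expression-matrix container used throughout the pipeline.

An :class:`ExpressionMatrix` wraps a pandas DataFrame (rows = gene common
names in ortholog-table order, columns = sample ids in metadata order) plus
two pieces of state the normalization stack needs:

* ``value_kind`` — what the numbers are (``raw_count``, ``fpkm``,
  ``gc_normalized``, ``depth_normalized``, ``log2``), so operations can
  refuse inputs at the wrong stage;
* ``library_size_proxy`` — the column sums of the *original, unfiltered*
  count matrix, captured once at assembly time and carried unchanged
  through filtering and normalization (depth normalization divides by
  these, scaled by the composition factors, not by the post-filter sums).

Every transforming operation appends a provenance entry, so a matrix
records the full chain of steps that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]

VALUE_KINDS = ("raw_count", "fpkm", "gc_normalized", "depth_normalized", "log2")


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame
    value_kind: str
    library_size_proxy: pd.Series | None = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.library_size_proxy is not None:
            missing = set(self.values.columns) - set(self.library_size_proxy.index)
            if missing:
                raise ValueError(f"library_size_proxy missing samples: {sorted(missing)}")
            self.library_size_proxy = self.library_size_proxy.reindex(
                self.values.columns
            ).astype(float)

    @property
    def gene_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def evolve(self, values: pd.DataFrame, value_kind: str, step: dict) -> "ExpressionMatrix":
        """New matrix with transformed values and one more provenance entry."""
        return ExpressionMatrix(
            values=values,
            value_kind=value_kind,
            library_size_proxy=self.library_size_proxy,
            provenance=self.provenance + [step],
        )

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path, sidecar: bool = True) -> None:
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="gene")
        if sidecar:
            meta = {
                "value_kind": self.value_kind,
                "library_size_proxy": (
                    None
                    if self.library_size_proxy is None
                    else self.library_size_proxy.to_dict()
                ),
                "provenance": self.provenance,
            }
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=2, default=str)
            )

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col="gene")
        sidecar = path.with_suffix(path.suffix + ".json")
        kind, proxy, prov = "raw_count", None, []
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            kind = meta.get("value_kind", kind)
            if meta.get("library_size_proxy"):
                proxy = pd.Series(meta["library_size_proxy"])
            prov = meta.get("provenance", [])
        return cls(values=values, value_kind=kind, library_size_proxy=proxy, provenance=prov)
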