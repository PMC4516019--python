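"""Per-gene GC content over the union of a gene's transcript exons.

For every gene the exons of all its transcripts are merged into a set of
disjoint intervals (adjacent intervals merge too, so the union is minimal),
and GC content is computed as (#G + #C) / (#A + #C + #G + #T) over the
merged exon sequence.  Ambiguity codes (N and friends) count in neither the
numerator nor the denominator.  Soft-masked lowercase bases count as their
uppercase equivalents.  Strand is ignored: G+C content is invariant under
reverse complement.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

__all__ = [
    "ExonInterval",
    "GeneGCRecord",
    "merge_exons",
    "gene_gc",
    "read_gtf_exons",
    "build_gc_table",
    "gc_table_to_frame",
]


@dataclass(frozen=True)
class ExonInterval:
    """A 1-based, inclusive exon interval attributed to a gene."""

    chrom: str
    start: int
    end: int
    gene_id: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"interval start > end: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneGCRecord:
    gene_id: str
    common_name: str
    gc_fraction: float  # NaN when unambiguous_length == 0
    unambiguous_length: int


def merge_exons(exons: Sequence[ExonInterval]) -> list[ExonInterval]:
    """Merge overlapping and book-ended intervals into a disjoint union.

    Intervals are merged per chromosome; the output is sorted by
    (chromosome, start).  Idempotent and order-invariant.
    """
    by_chrom: dict[str, list[ExonInterval]] = {}
    for e in exons:
        by_chrom.setdefault(e.chrom, []).append(e)
    merged: list[ExonInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda e: (e.start, e.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        gene_id = ivs[0].gene_id
        for e in ivs[1:]:
            if e.start <= cur_end + 1:  # overlap or adjacency
                cur_end = max(cur_end, e.end)
            else:
                merged.append(ExonInterval(chrom, cur_start, cur_end, gene_id))
                cur_start, cur_end = e.start, e.end
        merged.append(ExonInterval(chrom, cur_start, cur_end, gene_id))
    return merged


def gene_gc(merged: Sequence[ExonInterval], genome) -> tuple[float, int]:
    """GC fraction and unambiguous length of a gene's merged exons.

    ``genome`` is any mapping from chromosome name to an indexable
    sequence (a :class:`pyfaidx.Fasta` or a plain dict of strings).
    Returns ``(nan, 0)`` when no unambiguous base is covered.
    """
    gc = 0
    unambig = 0
    for iv in merged:
        try:
            seq = genome[iv.chrom][iv.start - 1 : iv.end]
        except KeyError:
            raise KeyError(
                f"chromosome {iv.chrom!r} not present in the genome sequence"
            ) from None
        seq = str(seq).upper()
        gc += seq.count("G") + seq.count("C")
        unambig += sum(seq.count(b) for b in "ACGT")
    if unambig == 0:
        return float("nan"), 0
    return gc / unambig, unambig


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_exons(gtf_path) -> list[tuple[ExonInterval, str]]:
    """Yield (interval, common_name) for every exon feature of a GTF file.

    Understands ENSEMBL/GENCODE attribute syntax (``key "value";``).  An
    exon without a ``gene_id`` attribute is an error naming the line; a
    missing ``gene_name`` falls back to the gene_id.
    """
    out: list[tuple[ExonInterval, str]] = []
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{gtf_path}:{lineno}: not a 9-column GTF line")
            if fields[2] != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(fields[8]))
            if "gene_id" not in attrs:
                raise ValueError(f"{gtf_path}:{lineno}: exon feature lacks gene_id")
            iv = ExonInterval(
                chrom=fields[0],
                start=int(fields[3]),
                end=int(fields[4]),
                gene_id=attrs["gene_id"],
            )
            out.append((iv, attrs.get("gene_name", attrs["gene_id"])))
    return out


def _harmonize_chrom(chrom: str, genome, rename: Mapping[str, str] | None) -> str:
    """Resolve GTF chromosome names against the FASTA (rename map, then a
    'chr' prefix add/strip pass)."""
    if rename and chrom in rename:
        chrom = rename[chrom]
    candidates = [chrom]
    if chrom.startswith("chr"):
        candidates.append(chrom[3:])
    else:
        candidates.append("chr" + chrom)
    for c in candidates:
        if c in genome:
            return c
    raise KeyError(
        f"chromosome {chrom!r} (tried {candidates}) not found in the genome FASTA"
    )


def build_gc_table(
    gtf_path,
    fasta,
    rename_chroms: Mapping[str, str] | None = None,
) -> list[GeneGCRecord]:
    """Compute one GC record per gene_id from a GTF and its genome FASTA.

    Records are returned in first-appearance order of the gene_id in the
    GTF; that order defines the "first appearance" used when several gene
    ids share a common name downstream.
    """
    genome = fasta if hasattr(fasta, "keys") else Fasta(str(fasta))
    exons = read_gtf_exons(gtf_path)
    per_gene: dict[str, list[ExonInterval]] = {}
    name_of: dict[str, str] = {}
    for iv, common in exons:
        chrom = _harmonize_chrom(iv.chrom, genome, rename_chroms)
        per_gene.setdefault(iv.gene_id, []).append(
            ExonInterval(chrom, iv.start, iv.end, iv.gene_id)
        )
        name_of.setdefault(iv.gene_id, common)
    records = []
    for gene_id, ivs in per_gene.items():
        gc, length = gene_gc(merge_exons(ivs), genome)
        if length == 0:
            logger.warning("gene %s covers no unambiguous bases; GC missing", gene_id)
        records.append(GeneGCRecord(gene_id, name_of[gene_id], gc, length))
    return records


def gc_table_to_frame(records: Sequence[GeneGCRecord]) -> pd.DataFrame:
    """GC records as a DataFrame (gene_id, common_name, gc_fraction,
    unambiguous_length), preserving record order."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "common_name": [r.common_name for r in records],
            "gc_fraction": [r.gc_fraction for r in records],
            "unambiguous_length": [r.unambiguous_length for r in records],
        }
    )
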