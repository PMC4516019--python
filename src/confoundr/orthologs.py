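"""One-to-one human-mouse ortholog extraction from a modENCODE-style table.

The ortholog file is whitespace-delimited; each record describes one
orthology group with comma-separated gene-name lists per species and, in
its last two columns, the number of genes the group draws from each
species.  One-to-one pairs are the records whose last two columns are both
"1".

Two parse modes are supported:

* ``strict`` — both of the last two columns must be exactly ``"1"``.
* ``prefix`` — the second-to-last column must be ``"1"`` but the last
  column need only *begin* with ``"1"`` (e.g. ``"12"``).  This reproduces
  a plausible command-line filtering slip (``grep`` on an unanchored
  pattern) and inflates the pair count; multi-gene groups admitted this
  way contribute their first-listed gene, which is then not a true
  one-to-one ortholog.  Prefix output is always a superset of strict
  output.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologRecord",
    "OrthologTable",
    "read_ortholog_records",
    "select_one_to_one",
    "intersect_with_annotation",
]


@dataclass
class OrthologRecord:
    human_genes: list[str]
    mouse_genes: list[str]
    raw_last_two: tuple[str, str]

    @property
    def n_human(self) -> int | None:
        try:
            return int(self.raw_last_two[0])
        except ValueError:
            return None

    @property
    def n_mouse(self) -> int | None:
        try:
            return int(self.raw_last_two[1])
        except ValueError:
            return None


@dataclass
class OrthologTable:
    pairs: list[tuple[str, str]]
    parse_mode: str
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def human_names(self) -> list[str]:
        return [h for h, _ in self.pairs]

    def mouse_names(self) -> list[str]:
        return [m for _, m in self.pairs]


def read_ortholog_records(
    source,
    human_col: int = 1,
    mouse_col: int = 2,
) -> list[OrthologRecord]:
    """Read ortholog-group records from a path or an iterable of lines.

    Fields are split on arbitrary whitespace runs.  ``human_col`` and
    ``mouse_col`` index the comma-separated gene-name list columns; the
    last two fields of every record are kept verbatim as the per-species
    group-size columns.  Records whose declared sizes disagree with the
    list lengths are logged, not rejected (real files contain such
    inconsistencies).
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        opener = gzip.open if str(source).endswith(".gz") else open
        with opener(source, "rt") as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    records: list[OrthologRecord] = []
    n_inconsistent = 0
    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        if not fields or line.lstrip().startswith("#"):
            continue
        if len(fields) < max(human_col, mouse_col) + 3:
            logger.warning("ortholog line %d: too few fields, skipped", lineno)
            continue
        rec = OrthologRecord(
            human_genes=fields[human_col].split(","),
            mouse_genes=fields[mouse_col].split(","),
            raw_last_two=(fields[-2], fields[-1]),
        )
        if rec.n_human is not None and rec.n_human != len(rec.human_genes):
            n_inconsistent += 1
        elif rec.n_mouse is not None and rec.n_mouse != len(rec.mouse_genes):
            n_inconsistent += 1
        records.append(rec)
    if n_inconsistent:
        logger.warning(
            "%d ortholog records declare group sizes inconsistent with their "
            "gene lists",
            n_inconsistent,
        )
    return records


def select_one_to_one(
    records: Sequence[OrthologRecord], mode: str = "strict"
) -> OrthologTable:
    """Extract one-to-one pairs under strict or prefix column matching.

    Duplicate gene names after selection (the same human or mouse name
    appearing in two retained records) keep their first occurrence, with a
    warning — the same first-appearance rule the expression-matrix builder
    uses.
    """
    if mode not in ("strict", "prefix"):
        raise ValueError(f"unknown parse mode {mode!r}")
    if not records:
        logger.warning("empty ortholog record list")
    pairs: list[tuple[str, str]] = []
    seen_h: set[str] = set()
    seen_m: set[str] = set()
    n_selected = n_collided = 0
    for rec in records:
        a, b = rec.raw_last_two
        if mode == "strict":
            keep = a == "1" and b == "1"
        else:
            keep = a == "1" and b.startswith("1")
        if not keep:
            continue
        n_selected += 1
        h, m = rec.human_genes[0], rec.mouse_genes[0]
        if h in seen_h or m in seen_m:
            n_collided += 1
            logger.warning("duplicate gene name in pair (%s, %s); keeping first", h, m)
            continue
        seen_h.add(h)
        seen_m.add(m)
        pairs.append((h, m))
    return OrthologTable(
        pairs=pairs,
        parse_mode=mode,
        provenance={
            "n_records": len(records),
            "n_selected": n_selected,
            "n_duplicate_collisions": n_collided,
            "n_pairs": len(pairs),
        },
    )


def intersect_with_annotation(
    table: OrthologTable, human_names: set[str], mouse_names: set[str]
) -> OrthologTable:
    """Keep pairs whose members both appear in the annotation gene sets."""
    if not human_names or not mouse_names:
        raise ValueError(
            "empty annotation gene-name set — wrong or unparsed annotation file?"
        )
    kept = [
        (h, m) for h, m in table.pairs if h in human_names and m in mouse_names
    ]
    prov = dict(table.provenance)
    prov.update(
        {
            "n_before_annotation_intersect": len(table.pairs),
            "n_after_annotation_intersect": len(kept),
        }
    )
    return OrthologTable(pairs=kept, parse_mode=table.parse_mode, provenance=prov)
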