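"""Sequencing study-design reconstruction from Illumina FASTQ identifiers.

Illumina read headers encode which machine, run, flowcell and lane a read
came from.  Samples multiplexed on the same lane of the same run share all
four, so grouping samples by that 4-tuple recovers the sequencing batches
even when the submitters published no batch metadata.  Two header dialects
exist, depending on the CASAVA pipeline version that produced the FASTQ:

pre-1.8::

    @<machine_id>:<lane>:<tile>:<x_coord>:<y_coord>#<index>/<read_#>

1.8 and later::

    @<machine_id>:<run>:<flowcell>:<lane>:<tile>:<x>:<y> <read>:<filtered>:<control>:<index>

The pre-1.8 dialect carries no run or flowcell field, so batches inferred
from it collapse to (machine, lane) — a documented limitation.

This module also quantifies how strongly the recovered batches are
confounded with a biological factor (species or tissue): a batch is "pure"
if all its samples share one factor level, and Cramér's V summarises the
batch x factor contingency table in a single number in [0, 1].
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)

__all__ = [
    "Dialect",
    "SeqIdentifier",
    "BatchKey",
    "SampleRecord",
    "StudyDesign",
    "ConfoundingReport",
    "IdentifierError",
    "detect_dialect",
    "parse_identifier",
    "format_identifier",
    "read_fastq_identifier",
    "infer_batches",
    "confounding_report",
]


class IdentifierError(ValueError):
    """Raised when a FASTQ identifier line cannot be parsed."""


class Dialect(str, Enum):
    PRE_1_8 = "pre_1_8"
    V1_8_PLUS = "v1_8_plus"


_V18_RE = re.compile(
    r"^@(?P<machine_id>[^:\s]+):(?P<run_number>[^:\s]+):(?P<flowcell_id>[^:\s]+)"
    r":(?P<lane>[^:\s]+):(?P<tile>[^:\s]+):(?P<x_coord>[^:\s]+):(?P<y_coord>[^:\s]+)"
    r" (?P<read_number>[^:\s]+):(?P<is_filtered>[^:\s]+):(?P<control_number>[^:\s]+)"
    r":(?P<index_sequence>[^:\s]*)$"
)
_PRE18_RE = re.compile(
    r"^@(?P<machine_id>[^:\s#]+):(?P<lane>[^:\s#]+):(?P<tile>[^:\s#]+)"
    r":(?P<x_coord>[^:\s#]+):(?P<y_coord>[^:\s#]+)"
    r"#(?P<index_sequence>[^/\s]+)/(?P<read_number>\S+)$"
)


@dataclass(frozen=True)
class SeqIdentifier:
    """One parsed FASTQ sequence-identifier line."""

    dialect: Dialect
    machine_id: str
    lane: int
    tile: int
    x_coord: int
    y_coord: int
    read_number: int
    index_sequence: str
    # v1_8_plus only
    run_number: int | None = None
    flowcell_id: str | None = None
    is_filtered: str | None = None
    control_number: int | None = None

    def batch_key(self) -> "BatchKey":
        return BatchKey(
            machine_id=self.machine_id,
            run_number="" if self.run_number is None else str(self.run_number),
            flowcell_id=self.flowcell_id or "",
            lane=self.lane,
        )


@dataclass(frozen=True, order=True)
class BatchKey:
    """The 4-tuple identifying one sequencing batch: machine, run, flowcell, lane.

    For the pre-1.8 dialect run and flowcell are unavailable and stored as
    empty strings, so batches degrade to (machine, lane).
    """

    machine_id: str
    run_number: str
    flowcell_id: str
    lane: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        run = self.run_number or "?"
        fc = self.flowcell_id or "?"
        return f"{self.machine_id}:{run}:{fc}:lane{self.lane}"


@dataclass
class SampleRecord:
    sample_id: str
    species: str
    tissue: str
    identifier_line: str | None = None


@dataclass
class StudyDesign:
    samples: list[SampleRecord]
    batch_of: dict[str, BatchKey]
    batch_labels: dict[BatchKey, int]

    @property
    def n_batches(self) -> int:
        return len(self.batch_labels)

    def batch_label_of(self, sample_id: str) -> int:
        return self.batch_labels[self.batch_of[sample_id]]

    def members(self, key: BatchKey) -> list[SampleRecord]:
        return [s for s in self.samples if self.batch_of[s.sample_id] == key]


@dataclass
class ConfoundingReport:
    factor_name: str
    contingency: pd.DataFrame  # batches x factor levels
    n_pure_batches: int
    purity: float
    cramers_v: float
    degenerate: bool = False


def detect_dialect(line: str) -> Dialect:
    """Classify a FASTQ identifier line by its structural shape.

    Field *contents* are not validated here; :func:`parse_identifier`
    reports per-field errors.
    """
    line = line.rstrip("\n")
    if not line.startswith("@"):
        raise IdentifierError(f"not a FASTQ identifier line (no leading '@'): {line!r}")
    if _V18_RE.match(line):
        return Dialect.V1_8_PLUS
    if _PRE18_RE.match(line):
        return Dialect.PRE_1_8
    raise IdentifierError(f"unrecognized identifier shape: {line!r}")


def _int_field(raw: str, name: str, line: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise IdentifierError(
            f"field {name!r} is not an integer ({raw!r}) in line {line!r}"
        ) from None


def parse_identifier(line: str) -> SeqIdentifier:
    """Parse one identifier line into its dialect-appropriate fields."""
    line = line.rstrip("\n")
    dialect = detect_dialect(line)
    if dialect is Dialect.V1_8_PLUS:
        m = _V18_RE.match(line)
        assert m is not None
        g = m.groupdict()
        read = _int_field(g["read_number"], "read_number", line)
        if read not in (1, 2):
            raise IdentifierError(f"read_number must be 1 or 2, got {read} in {line!r}")
        return SeqIdentifier(
            dialect=dialect,
            machine_id=g["machine_id"],
            run_number=_int_field(g["run_number"], "run_number", line),
            flowcell_id=g["flowcell_id"],
            lane=_int_field(g["lane"], "lane", line),
            tile=_int_field(g["tile"], "tile", line),
            x_coord=_int_field(g["x_coord"], "x_coord", line),
            y_coord=_int_field(g["y_coord"], "y_coord", line),
            read_number=read,
            is_filtered=g["is_filtered"],
            control_number=_int_field(g["control_number"], "control_number", line),
            index_sequence=g["index_sequence"],
        )
    m = _PRE18_RE.match(line)
    assert m is not None
    g = m.groupdict()
    read = _int_field(g["read_number"], "read_number", line)
    if read not in (1, 2):
        raise IdentifierError(f"read_number must be 1 or 2, got {read} in {line!r}")
    return SeqIdentifier(
        dialect=dialect,
        machine_id=g["machine_id"],
        lane=_int_field(g["lane"], "lane", line),
        tile=_int_field(g["tile"], "tile", line),
        x_coord=_int_field(g["x_coord"], "x_coord", line),
        y_coord=_int_field(g["y_coord"], "y_coord", line),
        read_number=read,
        index_sequence=g["index_sequence"],
    )


def format_identifier(ident: SeqIdentifier) -> str:
    """Inverse of :func:`parse_identifier` (round-trip identity)."""
    if ident.dialect is Dialect.V1_8_PLUS:
        return (
            f"@{ident.machine_id}:{ident.run_number}:{ident.flowcell_id}"
            f":{ident.lane}:{ident.tile}:{ident.x_coord}:{ident.y_coord}"
            f" {ident.read_number}:{ident.is_filtered}:{ident.control_number}"
            f":{ident.index_sequence}"
        )
    return (
        f"@{ident.machine_id}:{ident.lane}:{ident.tile}:{ident.x_coord}"
        f":{ident.y_coord}#{ident.index_sequence}/{ident.read_number}"
    )


def read_fastq_identifier(path, scan_all: bool = False) -> str:
    """Return the first identifier line of a (possibly gzipped) FASTQ file.

    With ``scan_all=True`` every identifier line in the file is parsed and
    an error is raised if the file mixes batch keys — a homogeneity check.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    first: str | None = None
    key = None
    with opener(path, "rt") as fh:
        for i, raw in enumerate(fh):
            if i % 4 != 0:
                continue
            line = raw.rstrip("\n")
            if first is None:
                first = line
                if not scan_all:
                    break
                key = parse_identifier(line).batch_key()
            else:
                k = parse_identifier(line).batch_key()
                if k != key:
                    raise IdentifierError(
                        f"{path}: mixed batch keys within one FASTQ file "
                        f"({key} vs {k} at record {i // 4})"
                    )
    if first is None:
        raise IdentifierError(f"{path}: empty FASTQ file")
    return first


def infer_batches(samples: Sequence[SampleRecord]) -> StudyDesign:
    """Group samples into sequencing batches from their identifier lines.

    Batch labels 1..B are assigned in order of first appearance in the
    input, so membership is permutation-invariant while labels are
    deterministic given the input order.  Mixing the two header dialects
    within one study is an error (their batch keys are not comparable).
    """
    if not samples:
        raise ValueError("no samples given")
    dialects = set()
    batch_of: dict[str, BatchKey] = {}
    batch_labels: dict[BatchKey, int] = {}
    for s in samples:
        if s.identifier_line is None:
            raise IdentifierError(f"sample {s.sample_id!r} has no identifier line")
        ident = parse_identifier(s.identifier_line)
        dialects.add(ident.dialect)
        if len(dialects) > 1:
            raise IdentifierError(
                "mixed identifier dialects within one study "
                f"(at sample {s.sample_id!r})"
            )
        key = ident.batch_key()
        if key not in batch_labels:
            batch_labels[key] = len(batch_labels) + 1
            logger.info("inferred batch %d: %s", batch_labels[key], key)
        batch_of[s.sample_id] = key
    return StudyDesign(samples=list(samples), batch_of=batch_of, batch_labels=batch_labels)


def confounding_report(design: StudyDesign, factor: str) -> ConfoundingReport:
    """Quantify confounding between batch and a biological factor.

    Reports the batch x factor contingency table, the number of "pure"
    batches (all samples share one level), the fraction of samples sitting
    in pure batches, and Cramér's V of the table.  A degenerate table
    (a single batch or a single factor level) has no defined V; it is
    reported as 1 with ``degenerate=True`` since a single-level grouping
    is by construction fully confounded.
    """
    if not design.samples:
        raise ValueError("empty design")
    if factor not in ("species", "tissue"):
        raise ValueError(f"unknown factor {factor!r}")
    rows = []
    for s in design.samples:
        rows.append((design.batch_label_of(s.sample_id), getattr(s, factor)))
    df = pd.DataFrame(rows, columns=["batch", factor])
    table = pd.crosstab(df["batch"], df[factor])
    pure = table.gt(0).sum(axis=1).eq(1)
    n_pure = int(pure.sum())
    purity = float(table.loc[pure[pure].index].to_numpy().sum()) / len(design.samples)
    degenerate = min(table.shape) < 2
    if degenerate:
        v = 1.0
    else:
        chi2 = chi2_contingency(table.to_numpy(), correction=False).statistic
        n = table.to_numpy().sum()
        v = float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))
    return ConfoundingReport(
        factor_name=factor,
        contingency=table,
        n_pure_batches=n_pure,
        purity=purity,
        cramers_v=v,
        degenerate=degenerate,
    )
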