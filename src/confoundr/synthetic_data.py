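"""Synthetic inputs emulating the confounded comparative RNA-seq study.

The emulated design: 26 samples = 13 tissues x 2 species, sequenced in
five multiplexed single-lane batches on four instruments —

* two human-only batches sharing machine, run and flowcell and differing
  only in lane number;
* one mixed batch carrying the last two human tissues plus two mouse
  samples (one of them the tissue counterpart of a mixed-batch human);
* two mouse-only batches on two further instruments.

Counts are negative-binomial around a log2-scale mean that is additive in
per-gene baseline, tissue, species and batch-location effects, with a
per-batch scale component (batch-dependent residual noise magnitude, so
scale shrinkage is exercised, not just centering), a per-sample smooth GC
bias curve, and log-normal library-size factors.  Every random draw is
produced from a single seeded generator, so a config (including its seed)
determines each output byte-for-byte, and all planted quantities are
recorded in a :class:`GroundTruth` for exact downstream checks.

Default effect scales (log2 units): tissue 1.0, species 0.5, batch 2.0 —
a technically dominated regime in which uncorrected samples group by
batch (and hence, given the confounding, by species), while the tissue
signal is recoverable once batches are adjusted for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .matrix_build import QuantTable
from .study_design import BatchKey, SampleRecord, format_identifier, SeqIdentifier, Dialect

logger = logging.getLogger(__name__)

__all__ = [
    "BatchSpec",
    "SimConfig",
    "GroundTruth",
    "figure_layout",
    "simulate_counts",
    "simulate_fastq_headers",
    "simulate_ortholog_file",
    "simulate_annotation",
    "simulate_quant_tables",
    "mouse_name",
    "ortholog_table_for",
]


@dataclass(frozen=True)
class BatchSpec:
    """One sequencing batch: its identifier key and its (species, tissue)
    sample slots."""

    key: BatchKey
    members: tuple[tuple[str, str], ...]


def figure_layout(n_tissues: int = 13) -> tuple[BatchSpec, ...]:
    """The study's five-batch confounded layout.

    Tissues are named T01..Tnn.  The two human-only batches share machine,
    run and flowcell (differing only in lane); the mixed batch holds four
    samples of both species; the two mouse-only batches sit on two other
    instruments.  Four machines in total.
    """
    if n_tissues < 4:
        raise ValueError("need at least 4 tissues for the five-batch layout")
    tissues = [f"T{i + 1:02d}" for i in range(n_tissues)]
    # The mixed batch holds the last two human tissues plus two mouse
    # samples, one sharing a tissue with a mixed-batch human sample.  This
    # keeps the design only *nearly* confounded: four of five batches are
    # species-pure, yet the cross-species pair inside the mixed lane makes
    # the batch + species + tissue model identifiable (full column rank)
    # instead of letting batch absorb species outright.
    mix_h = tissues[-2:]
    mix_m = [tissues[-2], tissues[0]]
    h_rest = [t for t in tissues if t not in mix_h]
    m_rest = [t for t in tissues if t not in mix_m]
    hh, mh = len(h_rest) // 2, len(m_rest) // 2
    return (
        BatchSpec(
            BatchKey("HSQ1", "201", "C10HUMAAXX", 4),
            tuple(("human", t) for t in h_rest[:hh]),
        ),
        BatchSpec(
            BatchKey("HSQ1", "201", "C10HUMAAXX", 5),
            tuple(("human", t) for t in h_rest[hh:]),
        ),
        BatchSpec(
            BatchKey("MSQ0", "310", "C20MIXAAXX", 1),
            tuple(("human", t) for t in mix_h) + tuple(("mouse", t) for t in mix_m),
        ),
        BatchSpec(
            BatchKey("MSQ1", "305", "C30MOUAAXX", 2),
            tuple(("mouse", t) for t in m_rest[:mh]),
        ),
        BatchSpec(
            BatchKey("MSQ2", "412", "C40MOUAAXX", 3),
            tuple(("mouse", t) for t in m_rest[mh:]),
        ),
    )


@dataclass
class SimConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    n_genes: int = 2000
    n_tissues: int = 13
    batch_layout: tuple[BatchSpec, ...] | None = None  # None -> figure_layout
    sd_tissue: float = 1.0
    sd_species: float = 0.5
    sd_batch: float = 2.0
    batch_scale_sd: float = 0.2
    sd_residual: float = 0.1
    gc_bias_amplitude: float = 1.0
    libsize_log_sd: float = 0.3
    nb_dispersion: float = 0.01
    n_mito: int = 12
    seed: int = 0

    def layout(self) -> tuple[BatchSpec, ...]:
        return (
            self.batch_layout
            if self.batch_layout is not None
            else figure_layout(self.n_tissues)
        )


@dataclass
class GroundTruth:
    base: pd.Series  # per-gene baseline log2 mean
    tissue_effect: pd.DataFrame  # genes x tissues
    species_effect: pd.DataFrame  # genes x species
    batch_location: pd.DataFrame  # genes x batch labels
    batch_scale: pd.Series  # per batch residual-noise multiplier
    residual_lognoise: np.ndarray  # genes x samples, drawn log2 noise
    gc: pd.Series  # per gene GC fraction
    gc_slope: pd.Series  # per sample log-linear GC-bias slope
    libsize_factor: pd.Series  # per sample
    mito_genes: list[str]
    sample_batch: pd.Series  # sample -> batch label (1..B)
    sample_species: pd.Series
    sample_tissue: pd.Series

    def expected_mean(self, genes: Sequence[str], samples: Sequence[str]) -> pd.DataFrame:
        """Deterministic NB mean of each (gene, sample) cell — the
        systematic part of the model, excluding drawn residual noise."""
        gc_centered = self.gc - float(self.gc.mean())
        out = {}
        for sid in samples:
            log2mu = (
                self.base
                + self.tissue_effect[self.sample_tissue[sid]]
                + self.species_effect[self.sample_species[sid]]
                + self.batch_location[self.sample_batch[sid]]
            )
            bias_full = np.exp(self.gc_slope[sid] * gc_centered)
            bias = bias_full / float(bias_full.mean())
            out[sid] = (self.libsize_factor[sid] * bias * np.exp2(log2mu)).loc[
                list(genes)
            ]
        return pd.DataFrame(out)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def simulate_counts(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, list[SampleRecord], "StudyDesignLite", GroundTruth]:
    """Draw a raw-count matrix under the confounded design.

    Returns (matrix, sample records, batch assignment, ground truth).  The
    matrix rows are ortholog common names GENE0001..; the first ``n_mito``
    high-baseline genes are designated mitochondrial (names MT-01..), so
    they land in the top expression stratum as in the real libraries.
    """
    layout = cfg.layout()
    for b in layout:
        if not b.members:
            raise ValueError(f"batch {b.key} has no samples")
    tissues = sorted({t for b in layout for _, t in b.members})
    species = sorted({s for b in layout for s, _ in b.members})
    for t in tissues:
        present = {s for b in layout for s, tt in b.members if tt == t}
        if present != set(species):
            raise ValueError(f"tissue {t} missing a species: has {sorted(present)}")

    rng = np.random.default_rng(cfg.seed)
    n_mito = min(cfg.n_mito, cfg.n_genes)
    genes = [f"MT-{i + 1:02d}" for i in range(n_mito)] + [
        f"GENE{i + 1:05d}" for i in range(cfg.n_genes - n_mito)
    ]
    G = cfg.n_genes

    base = rng.normal(4.0, 1.5, G)
    base[:n_mito] = rng.normal(9.0, 0.5, n_mito)  # mito genes dominate libraries
    tissue_eff = pd.DataFrame(
        rng.normal(0.0, cfg.sd_tissue, (G, len(tissues))), index=genes, columns=tissues
    )
    species_eff = pd.DataFrame(
        rng.normal(0.0, cfg.sd_species, (G, len(species))), index=genes, columns=species
    )
    batch_labels = list(range(1, len(layout) + 1))
    batch_loc = pd.DataFrame(
        rng.normal(0.0, cfg.sd_batch, (G, len(layout))),
        index=genes,
        columns=batch_labels,
    )
    batch_scale = pd.Series(
        np.exp(rng.normal(0.0, cfg.batch_scale_sd, len(layout))), index=batch_labels
    )
    gc = pd.Series(np.clip(rng.beta(4, 4, G) * 0.5 + 0.25, 0.0, 1.0), index=genes)

    samples: list[SampleRecord] = []
    sample_batch: dict[str, int] = {}
    for label, b in zip(batch_labels, layout):
        for sp, t in b.members:
            sid = f"{sp}_{t}"
            samples.append(SampleRecord(sample_id=sid, species=sp, tissue=t))
            sample_batch[sid] = label
    n_samples = len(samples)

    gc_slope = pd.Series(
        rng.uniform(-1.0, 1.0, n_samples) * cfg.gc_bias_amplitude,
        index=[s.sample_id for s in samples],
    )
    libsize = pd.Series(
        np.exp(rng.normal(0.0, cfg.libsize_log_sd, n_samples)),
        index=[s.sample_id for s in samples],
    )
    resid = rng.normal(0.0, 1.0, (G, n_samples))

    cols = {}
    gc_centered = gc.to_numpy() - float(gc.mean())
    for j, s in enumerate(samples):
        label = sample_batch[s.sample_id]
        log2mu = (
            base
            + tissue_eff[s.tissue].to_numpy()
            + species_eff[s.species].to_numpy()
            + batch_loc[label].to_numpy()
            + cfg.sd_residual * batch_scale[label] * resid[:, j]
        )
        bias = np.exp(gc_slope[s.sample_id] * gc_centered)
        bias = bias / bias.mean()
        mean = libsize[s.sample_id] * bias * np.exp2(log2mu)
        cols[s.sample_id] = _nb_draw(rng, mean, cfg.nb_dispersion)

    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    matrix = ExpressionMatrix(
        values=values,
        value_kind="raw_count",
        library_size_proxy=values.sum(axis=0),
        provenance=[{"step": "simulate_counts", "seed": cfg.seed, "n_genes": G}],
    )
    truth = GroundTruth(
        base=pd.Series(base, index=genes),
        tissue_effect=tissue_eff,
        species_effect=species_eff,
        batch_location=batch_loc,
        batch_scale=batch_scale,
        residual_lognoise=resid,
        gc=gc,
        gc_slope=gc_slope,
        libsize_factor=libsize,
        mito_genes=genes[:n_mito],
        sample_batch=pd.Series(sample_batch),
        sample_species=pd.Series({s.sample_id: s.species for s in samples}),
        sample_tissue=pd.Series({s.sample_id: s.tissue for s in samples}),
    )
    design = StudyDesignLite(
        batch_of={s.sample_id: layout[sample_batch[s.sample_id] - 1].key for s in samples},
        labels=sample_batch,
    )
    return matrix, samples, design, truth


@dataclass
class StudyDesignLite:
    """Planted batch assignment (the generator's ground-truth design)."""

    batch_of: dict[str, BatchKey]
    labels: dict[str, int]


def simulate_fastq_headers(
    layout: Sequence[BatchSpec] | None = None, seed: int = 0, n_tissues: int = 13
) -> dict[str, str]:
    """One valid CASAVA >= 1.8 identifier line per sample, encoding each
    sample's planted batch key; batch inference on these recovers the
    layout exactly."""
    if layout is None:
        layout = figure_layout(n_tissues)
    rng = np.random.default_rng(seed)
    lines: dict[str, str] = {}
    for b in layout:
        for sp, t in b.members:
            sid = f"{sp}_{t}"
            ident = SeqIdentifier(
                dialect=Dialect.V1_8_PLUS,
                machine_id=b.key.machine_id,
                run_number=int(b.key.run_number),
                flowcell_id=b.key.flowcell_id,
                lane=b.key.lane,
                tile=int(rng.integers(1101, 2316)),
                x_coord=int(rng.integers(1000, 30000)),
                y_coord=int(rng.integers(1000, 30000)),
                read_number=1,
                is_filtered="N",
                control_number=0,
                index_sequence="".join(rng.choice(list("ACGT"), 6)),
            )
            lines[sid] = format_identifier(ident)
    return lines


def simulate_ortholog_file(
    n_records: int,
    n_strict: int,
    n_prefix_only: int,
    seed: int = 0,
    path=None,
) -> tuple[list[str], dict]:
    """A modENCODE-style ortholog table with planted parse-mode counts.

    ``n_strict`` records are true one-to-one pairs (last two columns
    "1 1"); ``n_prefix_only`` are prefix traps whose last column begins
    with "1" but is not "1" (multi-gene mouse lists); the remainder get
    other group sizes.  Record order is shuffled.  Returns the lines and
    a ground-truth dict with the expected strict and prefix counts.
    """
    if n_strict + n_prefix_only > n_records:
        raise ValueError("n_strict + n_prefix_only must not exceed n_records")
    rng = np.random.default_rng(seed)
    lines = []
    for i in range(n_records):
        h = [f"HUM{i + 1:05d}"]
        if i < n_strict:
            mlist = [f"Mus{i + 1:05d}"]
            last = ("1", "1")
        elif i < n_strict + n_prefix_only:
            k = int(rng.integers(10, 14))  # 10..13: begins with "1", is not "1"
            mlist = [f"Mus{i + 1:05d}x{j}" for j in range(k)]
            last = ("1", str(k))
        else:
            kh = int(rng.integers(2, 5))
            km = int(rng.integers(2, 5))
            h = [f"HUM{i + 1:05d}x{j}" for j in range(kh)]
            mlist = [f"Mus{i + 1:05d}x{j}" for j in range(km)]
            last = (str(kh), str(km))
        lines.append(
            f"OG{i + 1:05d}\t{','.join(h)}\t{','.join(mlist)}\t{last[0]}\t{last[1]}\n"
        )
    order = rng.permutation(n_records)
    lines = [lines[i] for i in order]
    truth = {
        "n_records": n_records,
        "strict_count": n_strict,
        "prefix_count": n_strict + n_prefix_only,
    }
    if path is not None:
        with open(path, "w") as fh:
            fh.writelines(lines)
    return lines, truth


def simulate_annotation(
    n_genes: int, seed: int = 0, chrom_len: int = 10000, n_chroms: int = 2
) -> tuple[str, str, pd.DataFrame]:
    """A toy GTF + FASTA pair with planted per-gene GC ground truth.

    Chromosomes are random ACGT with occasional N runs and soft-masked
    stretches; each gene has 1-5 transcripts with deliberately
    overlapping exons.  The returned frame records each gene's GC
    fraction and unambiguous length, computed by direct per-base
    counting at generation time.
    """
    rng = np.random.default_rng(seed)
    chroms = {}
    for c in range(n_chroms):
        seq = rng.choice(list("ACGT"), chrom_len)
        # plant a few N runs
        for _ in range(3):
            start = int(rng.integers(0, chrom_len - 50))
            seq[start : start + int(rng.integers(5, 40))] = "N"
        # soft-mask a stretch
        start = int(rng.integers(0, chrom_len - 200))
        seq[start : start + 200] = [b.lower() for b in seq[start : start + 200]]
        chroms[f"chr{c + 1}"] = "".join(seq)

    gtf_lines = []
    truth_rows = []
    for g in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        gene_id = f"ENSX{g + 1:08d}"
        name = f"Toy{g + 1}"
        gstart = int(rng.integers(1, chrom_len - 600))
        n_tx = int(rng.integers(1, 6))
        covered: set[int] = set()
        for t in range(n_tx):
            tx_id = f"{gene_id}.t{t + 1}"
            pos = gstart + int(rng.integers(0, 100))
            for _ in range(int(rng.integers(1, 4))):
                length = int(rng.integers(30, 150))
                end = min(pos + length, chrom_len)
                gtf_lines.append(
                    f"{chrom}\ttoy\texon\t{pos}\t{end}\t.\t+\t.\t"
                    f'gene_id "{gene_id}"; transcript_id "{tx_id}"; gene_name "{name}";\n'
                )
                covered.update(range(pos, end + 1))
                pos = end + int(rng.integers(2, 80))
                if pos >= chrom_len:
                    break
        seq = chroms[chrom]
        bases = [seq[p - 1].upper() for p in sorted(covered)]
        unambig = sum(b in "ACGT" for b in bases)
        gcn = sum(b in "GC" for b in bases)
        truth_rows.append(
            {
                "gene_id": gene_id,
                "common_name": name,
                "gc_fraction": (gcn / unambig) if unambig else float("nan"),
                "unambiguous_length": unambig,
            }
        )
    fasta = "".join(
        f">{c}\n" + "\n".join(s[i : i + 70] for i in range(0, len(s), 70)) + "\n"
        for c, s in chroms.items()
    )
    return "".join(gtf_lines), fasta, pd.DataFrame(truth_rows)


def simulate_quant_tables(
    matrix: ExpressionMatrix,
    samples: Sequence[SampleRecord],
    seed: int = 0,
    n_retired_human: int = 27,
    n_retired_mouse: int = 64,
    n_dup: int = 5,
) -> dict:
    """Per-species quantifier tables and GC/id tables from a common-name matrix.

    Expands the common-name count matrix into per-sample featureCounts-style
    tables keyed by species-specific gene ids, planting ``n_retired_*``
    retired identifiers (present in the GC table and the quant output, to
    be dropped) and ``n_dup`` live duplicate ids per species sharing a
    common name (first appearance wins).  Returns quant tables, GC tables,
    retired-id sets and the planted bookkeeping.
    """
    rng = np.random.default_rng(seed)
    genes = matrix.gene_names
    out = {"human": {}, "mouse": {}}
    gc_tables = {}
    retired = {}
    for species, prefix in (("human", "ENSG"), ("mouse", "ENSMUSG")):
        n_ret = n_retired_human if species == "human" else n_retired_mouse
        # mouse orthologs carry their own common names (lower-case style)
        names = genes if species == "human" else [mouse_name(g) for g in genes]
        live_ids = [f"{prefix}{i + 1:011d}" for i in range(len(names))]
        rows = [{"gene_id": gid, "common_name": g} for gid, g in zip(live_ids, names)]
        # retired ids: extra ids re-using existing common names
        ret_ids = [f"{prefix}9{i + 1:010d}" for i in range(n_ret)]
        ret_names = list(rng.choice(names, n_ret, replace=False))
        rows += [
            {"gene_id": gid, "common_name": nm} for gid, nm in zip(ret_ids, ret_names)
        ]
        # live duplicates: second live id for a common name (appears later)
        dup_ids = [f"{prefix}8{i + 1:010d}" for i in range(n_dup)]
        dup_names = list(rng.choice(names, n_dup, replace=False))
        rows += [
            {"gene_id": gid, "common_name": nm} for gid, nm in zip(dup_ids, dup_names)
        ]
        gc_tables[species] = pd.DataFrame(rows).assign(
            gc_fraction=0.5, unambiguous_length=1000
        )
        retired[species] = set(ret_ids)
        name_to_live = dict(zip(genes, live_ids))  # keyed by matrix row names
        for s in samples:
            if s.species != species:
                continue
            col = matrix.values[s.sample_id]
            vals = {name_to_live[g]: float(col[g]) for g in genes}
            for gid in ret_ids:
                vals[gid] = float(rng.integers(0, 50))
            for gid in dup_ids:
                vals[gid] = float(rng.integers(0, 50))
            out[species][s.sample_id] = QuantTable(
                sample_id=s.sample_id,
                values=pd.Series(vals),
                value_kind="raw_count",
            )
    return {
        "quants": {**out["human"], **out["mouse"]},
        "gc_tables": gc_tables,
        "retired": retired,
        "planted": {
            "n_retired_human": n_retired_human,
            "n_retired_mouse": n_retired_mouse,
            "n_dup": n_dup,
        },
    }


def mouse_name(human_name: str) -> str:
    """The synthetic mouse common name paired with a human common name."""
    return human_name.lower()


def ortholog_table_for(matrix: ExpressionMatrix):
    """One-to-one ortholog table matching the synthetic gene names."""
    from .orthologs import OrthologTable

    return OrthologTable(
        pairs=[(g, mouse_name(g)) for g in matrix.gene_names],
        parse_mode="strict",
        provenance={"source": "synthetic"},
    )
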