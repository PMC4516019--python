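#!/usr/bin/env python
"""Reconstruct the sequencing batches from FASTQ identifier lines.

Reads results/sim/samples.tsv, infers the batch of every sample from its
identifier line (machine, run, flowcell, lane), and quantifies how
strongly batch is confounded with species and with tissue.  Writes
results/design.json.
"""

import json
from pathlib import Path

import pandas as pd

from confoundr.study_design import SampleRecord, confounding_report, infer_batches

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    meta = pd.read_csv(ROOT / "sim" / "samples.tsv", sep="\t")
    samples = [
        SampleRecord(r.sample_id, r.species, r.tissue, r.identifier_line)
        for r in meta.itertuples()
    ]
    design = infer_batches(samples)
    print(f"inferred {design.n_batches} sequencing batches:")
    for key, label in design.batch_labels.items():
        members = [s.sample_id for s in design.members(key)]
        print(f"  batch {label} ({key}): {len(members)} samples")

    payload = {
        "n_batches": design.n_batches,
        "batch_of": {s: design.batch_label_of(s) for s in meta.sample_id},
    }
    for factor in ("species", "tissue"):
        rep = confounding_report(design, factor)
        payload[f"confounding_{factor}"] = {
            "n_pure_batches": rep.n_pure_batches,
            "purity": rep.purity,
            "cramers_v": rep.cramers_v,
        }
        print(
            f"{factor}: {rep.n_pure_batches}/{design.n_batches} pure batches, "
            f"purity {rep.purity:.3f}, Cramer's V {rep.cramers_v:.3f}"
        )
    (ROOT / "design.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {ROOT / 'design.json'}")


if __name__ == "__main__":
    main()
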