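import numpy as np
import pandas as pd
import pytest

from confoundr import synthetic_data as sim
from confoundr.study_design import SampleRecord


@pytest.fixture(scope="session")
def figure_samples():
    """The 26 samples of the confounded five-batch layout, with planted
    FASTQ identifier lines."""
    layout = sim.figure_layout()
    headers = sim.simulate_fastq_headers(layout, seed=7)
    samples = []
    for b in layout:
        for sp, t in b.members:
            sid = f"{sp}_{t}"
            samples.append(
                SampleRecord(sample_id=sid, species=sp, tissue=t, identifier_line=headers[sid])
            )
    return samples


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study (400 genes) shared by read-only tests."""
    cfg = sim.SimConfig(n_genes=400, seed=11)
    matrix, samples, design, truth = sim.simulate_counts(cfg)
    return {"cfg": cfg, "matrix": matrix, "samples": samples, "design": design, "truth": truth}
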