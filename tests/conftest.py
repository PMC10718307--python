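"""Shared fixtures: a small, fast synthetic dataset and its pipeline run."""

import numpy as np
import pandas as pd
import pytest

from hubweaver.matrix import ContactMatrix
from hubweaver.pipeline import RunConfig, run_all
from hubweaver.simulate import SimulationConfig, simulate_dataset, write_fixture


def small_config(**overrides) -> SimulationConfig:
    """Desk-scale config: 2 x 8 Mb at 40-kb bins (200 bins per chromosome)."""
    kwargs = dict(
        genome_spec=(("chr1", 8_000_000), ("chr2", 8_000_000)),
        n_tf_peaks=60,
        n_genes=120,
        n_distal_anchors=300,
        n_de_novo_peaks=12,
        n_tads=8,
        compartment_block_size=20,
        n_ep_targets=8,
        n_ebp_targets=5,
        seed=11,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def fixture_dir(small_dataset, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(small_dataset, d)
    return d


@pytest.fixture(scope="session")
def pipeline_report(fixture_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    return run_all(RunConfig(input_dir=str(fixture_dir), out_dir=str(out))), out


def symmetric_matrix(values: np.ndarray, chrom: str = "chrT", bin_size: int = 40_000) -> ContactMatrix:
    return ContactMatrix(chrom=chrom, bin_size=bin_size, matrix=np.asarray(values, float))


def toy_loops(rows) -> pd.DataFrame:
    """Loop table from (chrom, s1, e1, s2, e2, extra-dict) tuples."""
    recs = []
    for chrom, s1, e1, s2, e2, extra in rows:
        rec = dict(chrom1=chrom, start1=s1, end1=e1, chrom2=chrom, start2=s2, end2=e2)
        rec.update(extra)
        recs.append(rec)
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    return pd.DataFrame(recs, columns=cols if not recs else None)
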