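"""Shared fixtures: a small simulated cohort and hand-built transcript pairs."""

from __future__ import annotations

import dataclasses

import pytest

from splicegbm.dataset import build_dataset
from splicegbm.genomic_io import Genome, read_annotation, read_variants
from splicegbm.synthetic_fixtures import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A 10-gene cohort with 80+80 planted variants (seed 11)."""
    out = tmp_path_factory.mktemp("sim_small")
    cfg = SimulationConfig(seed=11, n_genes=10, n_pathogenic=80, n_common=80)
    paths = simulate_all(cfg, out)
    genome = Genome(paths["fasta"])
    models = read_annotation(paths["gtf"])
    records = read_variants(paths["tsv"])
    return {
        "cfg": cfg,
        "paths": paths,
        "genome": genome,
        "models": models,
        "records": records,
    }


@pytest.fixture(scope="session")
def sim_ds(sim_small):
    return build_dataset(
        sim_small["records"], sim_small["models"], sim_small["genome"]
    )


@pytest.fixture(scope="session")
def overlapping_pair(sim_small):
    """Two transcripts with identical intron boundaries on one fixture gene,
    so every acceptor window is shared by both."""
    tm = sim_small["models"][0]
    twin = dataclasses.replace(tm, transcript_id=tm.transcript_id + "_twin")
    return [tm, twin]


@pytest.fixture()
def tiny_fasta(tmp_path):
    """Single 6-nt contig for slice/orientation checks."""
    p = tmp_path / "tiny.fa"
    p.write_text(">t1\nACGTAC\n")
    return p
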