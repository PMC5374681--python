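import logging

import numpy as np
import pytest

from panelfilter import (
    Amplicon,
    RunConfig,
    assign_genotypes,
    build_catalog,
    make_diploid_sequences,
    random_panel,
    run_pipeline,
)

logging.getLogger("panelfilter").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_panel():
    return random_panel(2, 120, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_panel):
    catalog = build_catalog(small_panel, n_snv=6, n_indel=3, seed=12)
    return assign_genotypes(catalog, ["A", "B", "C"], seed=13)


@pytest.fixture(scope="session")
def small_diploid(small_panel, small_truth):
    return make_diploid_sequences(small_panel, small_truth, "A", seed=14)


@pytest.fixture
def homopolymer_amplicon():
    # AAAAA run embedded in an otherwise run-free context
    seq = "ACGTACGTACGTAAAAACGTACGTACGTACGT"
    return Amplicon(id="hp", chrom="chrHP", start=1, sequence=seq)


@pytest.fixture(scope="session")
def tiny_pipeline(tmp_path_factory):
    """A small but complete pipeline run shared across tests."""
    config = RunConfig(
        seed=42,
        n_samples=4,
        n_replicates=2,
        n_amplicons=3,
        amplicon_length=300,
    )
    outdir = tmp_path_factory.mktemp("tiny_run")
    return run_pipeline(config, outdir), outdir
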