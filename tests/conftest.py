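from __future__ import annotations

import numpy as np
import pytest

from mirprof import pipeline, simdata

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def sim_dataset():
    """One seeded synthetic dataset shared by the integration tests."""
    cfg = simdata.SimConfig(seed=FIXTURE_SEED)
    genome, model, refs, truth, reads = simdata.simulate_dataset(cfg)
    return cfg, genome, model, refs, truth, reads


@pytest.fixture(scope="session")
def sim_result(sim_dataset):
    """The shared dataset run through the full per-sample pipeline."""
    _, genome, model, refs, truth, reads = sim_dataset
    return pipeline.run_sample(
        "N1", tag_records=reads, reference_sets=refs, genome=genome, gene_model=model
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(FIXTURE_SEED)
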