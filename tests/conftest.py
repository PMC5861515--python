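"""Shared fixtures: one synthetic study bundle reused across the suite."""

import pytest

from chimscan import (PipelineConfig, ReadSimConfig, make_annotation,
                      make_genome, plant_chimeras, run_pipeline,
                      simulate_reads)
from chimscan.genomeindex import build_index


@pytest.fixture(scope="session")
def genome():
    return make_genome(3, 50_000, seed=11)


@pytest.fixture(scope="session")
def models(genome):
    return make_annotation(genome, 24, seed=12)


@pytest.fixture(scope="session")
def chimeras(genome, models):
    return plant_chimeras(genome, models, [1, 2, 3, 4], seed=13)


@pytest.fixture(scope="session")
def sim_bundle(chimeras):
    """Error-free stranded PE reads at 30x over every fusion transcript."""
    cfg = ReadSimConfig(depth=30.0, error_rate=0.0, seed=14)
    return simulate_reads(
        {c.label: c.fusion_transcript for c in chimeras}, cfg,
        junctions={c.label: c.junction_offset for c in chimeras})


@pytest.fixture(scope="session")
def index(genome):
    return build_index(genome, 22)


@pytest.fixture(scope="session")
def pipeline_result(genome, models, sim_bundle):
    config = PipelineConfig(k=22, sample="sim")
    return run_pipeline(config, genome, models, sim_bundle.read_pairs())
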