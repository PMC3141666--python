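"""Shared fixtures: the default synthetic study conditions, run once."""

from __future__ import annotations

import pytest

from mirloop.config import PipelineConfig
from mirloop.discovery import discover
from mirloop.mapping import GenomeIndex, map_and_filter
from mirloop.simulate import (
    SyntheticConfig,
    generate_genome_and_truth,
    libraries_to_reads,
    simulate_libraries,
)
from mirloop.tags import collapse_reads, filter_tags


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def synthetic_bundle():
    """Default synthetic study conditions: seed 7, 20 planted hairpins."""
    cfg = SyntheticConfig(seed=7, n_hairpins=20)
    genome, truth, features = generate_genome_and_truth(cfg)
    return cfg, genome, truth, features


@pytest.fixture(scope="session")
def discovery_run(synthetic_bundle, default_config):
    """Full discovery chain on the default synthetic conditions."""
    cfg, genome, truth, features = synthetic_bundle
    libraries = simulate_libraries(truth, cfg, genome)
    tags = filter_tags(collapse_reads(libraries_to_reads(libraries)), default_config)
    index = GenomeIndex(genome)
    mapped = map_and_filter(tags, index, default_config)
    candidates = discover(mapped, index, features, default_config)
    return {
        "config": cfg,
        "genome": genome,
        "truth": truth,
        "features": features,
        "libraries": libraries,
        "tags": tags,
        "index": index,
        "mapped": mapped,
        "candidates": candidates,
    }
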