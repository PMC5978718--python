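import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nicheshift.pipeline import RunConfig, run_pipeline
from nicheshift.synthetic_world import (GenoSimParams, PhenoSimParams,
                                        WorldConfig, make_world)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world_config():
    """A compact single-invasion world used across module tests."""
    return WorldConfig(seed=11, n_native_pops=10, n_source_pops=5,
                       n_invaded_pops=8)


@pytest.fixture(scope="session")
def small_world(small_world_config):
    return make_world(small_world_config)


@pytest.fixture(scope="session")
def small_run_config(tmp_path_factory):
    """A fast full-pipeline configuration (few thalli, one stressor set)."""
    out = tmp_path_factory.mktemp("run")
    return RunConfig(
        seed=5,
        outdir=str(out),
        world=WorldConfig(n_native_pops=10, n_source_pops=5, n_invaded_pops=8),
        genotypes=GenoSimParams(clone_fraction=0.25, haploid_fraction=0.1,
                                thalli_per_pop=8),
        phenotypes=PhenoSimParams(thalli_per_pop=8),
    )


@pytest.fixture(scope="session")
def pipeline_state(small_run_config):
    return run_pipeline(small_run_config)
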