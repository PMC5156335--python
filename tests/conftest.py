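import numpy as np
import pytest

from xema import (
    Basin,
    BirdInput,
    PipelineConfig,
    SimulationParams,
    run_pipeline,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_cohort(config):
    """Four birds (3 Pacific, 1 Atlantic) with default noise."""
    return simulate_cohort(config, 3, 1, seed=11)


@pytest.fixture(scope="session")
def cohort_result(config, small_cohort):
    inputs = [
        BirdInput(b.itinerary.bird_id, b.twilights, b.sst_samples, b.itinerary.sex, b.itinerary.deployment_year)
        for b in small_cohort.birds
    ]
    return run_pipeline(config, inputs, small_cohort.grids)


@pytest.fixture(scope="session")
def noiseless_params():
    return SimulationParams(
        twilight_noise_sd_min=0.0,
        sst_noise_sd_c=0.0,
        sst_missing_rate=0.0,
    )
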