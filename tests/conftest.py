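import numpy as np
import pytest
from hypothesis import settings

import baccgh as b

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def genome():
    return b.make_genome_model(include_y=True)


@pytest.fixture(scope="session")
def design_full(genome):
    """Default-size array: 2,464 clones in triplicate."""
    return b.generate_array_design(genome, 2464, seed=0)


@pytest.fixture(scope="session")
def design_small(genome):
    """Reduced array for fast unit tests."""
    return b.generate_array_design(genome, 300, seed=0)


@pytest.fixture(scope="session")
def zero_noise():
    return b.NoiseParams(sigma_clone=0.0, sigma_spot=0.0, outlier_prob=0.0,
                         outlier_sigma=0.0)


def run_pipeline(design, truth, noise, seed, seg_config=None,
                 calling_config=None):
    """simulate -> summarize -> QC -> drop Y -> segment -> call."""
    spots = b.simulate_spot_table(design, truth, noise, seed)
    profile = b.summarize_replicates(spots, design)
    profile = b.qc_filter(profile)
    profile = b.drop_chromosome(profile, "Y")
    segments = b.segment_profile(
        profile, seg_config or b.SegmentationConfig(seed=seed))
    calls = b.call_segments(segments, calling_config or b.CallingConfig(),
                            truth.test_sex, truth.reference_sex)
    return profile, segments, calls


def states_by_clone(calls):
    """clone_id -> called state name, from segment membership."""
    return {cid: c.state.name for c in calls for cid in c.segment.clone_ids}
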