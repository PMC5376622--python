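import numpy as np
import pytest

import flashmvpa as fm


@pytest.fixture(scope="session")
def small_dataset():
    """One reduced-size dataset with the default encoding (V1 kappa=0.2,
    control ROI kappa=0), shared across read-only tests."""
    return fm.generate_dataset(fm.small_config(), seed=101)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """Per-participant GLM fits of the shared small dataset."""
    from flashmvpa.pipeline import PipelineConfig, fit_participants

    params = PipelineConfig(seed=11, n_perms=50, n_boot=50, n_clusters=10)
    return fit_participants(small_dataset, params), params


def simulate_participant(config, rng, motion=False):
    """One participant's (schedule, Y, motion_params) without the dataset
    wrapper — the light path used by calibration tests."""
    from flashmvpa.synth import (build_schedule, generate_betas,
                                 generate_motion_params, generate_timeseries)

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    schedule = build_schedule(config, rng)
    betas, truth = generate_betas(config, rng)
    mp = generate_motion_params(config, rng) if motion else None
    Y = generate_timeseries(betas, schedule, config, rng, motion_params=mp)
    return schedule, Y, mp, betas, truth
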