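import numpy as np
import pytest

from nirsmark import pipeline, synth_cohort as sc


@pytest.fixture(scope="session")
def default_schedule():
    return sc.generate_schedule(33, 33, 33, seed=1)


@pytest.fixture(scope="session")
def clean_recording(default_schedule):
    """Zero-noise subject with a uniform 0.5 uM response on every channel."""
    truth = sc.GroundTruth.null()
    truth.amplitude[:, :] = 0.5
    return sc.simulate_subject(
        default_schedule, truth, sc.NoiseParams.silent(), age=30.0, seed=0
    )


@pytest.fixture(scope="session")
def small_cohort():
    """6 healthy + 6 TBI with the default group effect, one fixed seed."""
    recs, truths = sc.generate_cohort(6, 6, sc.EffectSpec(), seed=11)
    return recs, truths


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    recs, _ = small_cohort
    table = pipeline.cohort_temporal_table(recs)
    X = table.drop(columns=["subject", "group"])
    y = table["group"].to_numpy()
    return table, X, y


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
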