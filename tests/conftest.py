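import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phonoscreen as ps

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free, jitter-free cohort config at a fixed 60 bpm."""
    return ps.SynthCohortConfig(
        heart_rate_mean=60.0,
        heart_rate_sd=0.0,
        cycle_jitter_sd=0.0,
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def quiet_subject(quiet_config):
    """One noise-free normal-pressure subject (20 s, 60 bpm)."""
    rng = np.random.default_rng(1234)
    return ps.generate_subject(quiet_config, 17.0, "quiet", rng)


@pytest.fixture(scope="session")
def small_cohort_features():
    """Well-separated 8+8 cohort with per-subject features, labels, mPAp."""
    cfg = ps.SynthCohortConfig(n_subjects_ph=8, n_subjects_normal=8, seed=7)
    recs, meta = ps.generate_cohort(cfg)
    feats = ps.cohort_features(recs)
    labels = dict(zip(meta.subject_id, meta.label))
    mpap = dict(zip(meta.subject_id, meta.mpap.astype(float)))
    return feats, labels, mpap
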