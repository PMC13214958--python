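import numpy as np
import pytest

from sskeca.events import (
    BlinkEvent,
    FixationEvent,
    GazeSample,
    SaccadeEvent,
    TrialRecord,
)
from sskeca.synth import SyntheticProfile, generate_feature_table


def make_trial(
    subject="S01",
    group="HC",
    trial_id=1,
    fixations=None,
    saccades=None,
    blinks=None,
    samples=None,
    **kw,
):
    """Hand-buildable trial with sane defaults: 3 in-bounds fixations,
    2 saccades, 1 blink and a 10-sample pupil trace."""
    if fixations is None:
        fixations = [
            FixationEvent(100, 200, 400, 300, 23.0, 22.7, 1800),
            FixationEvent(400, 150, 350, 250, 23.1, 22.6, 1850),
            FixationEvent(700, 300, 450, 350, 23.0, 22.8, 1900),
        ]
    if saccades is None:
        saccades = [SaccadeEvent(300, 6, 4.0, 140.0), SaccadeEvent(550, 7, 5.0, 150.0)]
    if blinks is None:
        blinks = [BlinkEvent(1100, 120)]
    if samples is None:
        samples = [
            GazeSample(float(t), 400.0 + t, 300.0, 1500.0 + 50 * t) for t in range(1, 11)
        ]
    return TrialRecord(
        subject_id=subject,
        group=group,
        trial_id=trial_id,
        image_id=kw.pop("image_id", 1),
        category_id=kw.pop("category_id", 1),
        fixations=list(fixations),
        saccades=list(saccades),
        blinks=list(blinks),
        samples=list(samples),
        **kw,
    )


@pytest.fixture
def trial():
    return make_trial()


@pytest.fixture(scope="session")
def small_profile():
    """18 subjects x 6 trials: enough structure for fast pipeline tests."""
    return SyntheticProfile(n_sz=8, n_hc=10, trials_per_subject=6)


@pytest.fixture(scope="session")
def small_table(small_profile):
    return generate_feature_table(small_profile, seed=42)


@pytest.fixture(scope="session")
def medium_table():
    """90 subjects x 6 trials, the cohort geometry at reduced trial count."""
    return generate_feature_table(SyntheticProfile(trials_per_subject=6), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
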