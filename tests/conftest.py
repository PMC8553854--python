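import numpy as np
import pytest

from erpstates import (
    EffectSpec,
    Timeline,
    TruthManifest,
    make_templates,
)

DURS = [80.0, 100.0, 120.0, 100.0, 100.0, 100.0]
TIDS = ["T1", "T2", "T3", "T4", "T1", "T3"]


@pytest.fixture(scope="session")
def timeline() -> Timeline:
    """Six segments covering [0, 600) ms with recurring templates."""
    return Timeline.from_durations(DURS, TIDS, 0.0)


@pytest.fixture(scope="session")
def small_manifest(timeline) -> TruthManifest:
    """Moderate-noise study with a 60 deg effect in segment index 2."""
    return TruthManifest(
        template_set=make_templates(4, 30, 45, seed=3),
        timeline=timeline,
        effect_spec=EffectSpec(affected_segments=(2,), angle_deg=60.0),
        n_subjects=8,
        n_epochs_per_condition=10,
        noise_sd=10.0,
        subject_sd=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_manifest(timeline) -> TruthManifest:
    """Same design with all randomness in the data switched off."""
    return TruthManifest(
        template_set=make_templates(4, 30, 45, seed=3),
        timeline=timeline,
        effect_spec=EffectSpec(affected_segments=(2,), angle_deg=60.0),
        n_subjects=3,
        n_epochs_per_condition=4,
        noise_sd=0.0,
        subject_sd=0.0,
        seed=7,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
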