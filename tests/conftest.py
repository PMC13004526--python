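import numpy as np
import pytest

from thetagaze import eye, synth


@pytest.fixture(scope="session")
def default_session():
    """One synthetic session at generator defaults (shared, read-only)."""
    bundle, truth = synth.gen_session(seed=1, duration_s=120.0, n_channels=2,
                                      n_trials=4)
    return bundle, truth


@pytest.fixture(scope="session")
def classified(default_session):
    bundle, truth = default_session
    feats = eye.compute_kinematics(bundle.gaze)
    labels = eye.classify_samples(feats, seed=0)
    events = eye.events_from_labels(labels.t, labels.label,
                                    bundle.gaze.x, bundle.gaze.y)
    labels = eye.SampleLabels(t=labels.t, label=labels.label, events=events)
    return feats, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
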