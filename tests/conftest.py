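import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 50.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_window():
    """100-sample window: 3 Hz sinusoid of amplitude 2 on x, quiet y/z."""
    from wearsense import Window

    t = np.arange(100) / FS
    x = 2.0 * np.sin(2 * np.pi * 3.0 * t)
    samples = np.column_stack([x, 0.1 * np.sin(2 * np.pi * 5 * t), np.full(100, 9.81)])
    return Window(samples=samples, fs=FS, label="flapping")


@pytest.fixture(scope="session")
def small_feature_dataset():
    """A small but separable featurized dataset shared across classifier tests."""
    from wearsense import feature_matrix, generate_dataset, segment_windows

    recs = generate_dataset(n_per_class=12, duration=2.0, fs=FS, n_subjects=4, seed=11)
    windows = [w for r in recs for w in segment_windows(r)]
    X, labels = feature_matrix(windows)
    return X, np.asarray(labels)
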