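import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myobench import ProtocolConfig, SyntheticConfig, extract_features
from myobench.synthetic_emg import generate_session

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_session():
    """One full-size synthetic subject (10 movements, 4 channels, 1000 Hz)."""
    return generate_session(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_features(default_session):
    return extract_features(default_session)


@pytest.fixture(scope="session")
def small_protocol():
    """A reduced protocol for fast I/O and plumbing tests."""
    return ProtocolConfig(
        movements=("open hand", "close hand", "pronation"),
        contraction_s=1.5,
        relax_s=1.0,
        repetitions=2,
    )


@pytest.fixture(scope="session")
def small_session(small_protocol):
    return generate_session(SyntheticConfig(protocol=small_protocol, seed=3))


def make_separable_dataset(seed, n_classes=5, n_per_class=40, d=8, spacing=6.0):
    """Well-separated Gaussian blobs: class means `spacing` apart, unit noise."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=spacing, size=(n_classes, d))
    X = np.vstack([centers[k] + rng.standard_normal((n_per_class, d))
                   for k in range(n_classes)])
    y = np.repeat([f"class{k}" for k in range(n_classes)], n_per_class)
    perm = rng.permutation(len(y))
    return X[perm], y.astype(object)[perm]
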