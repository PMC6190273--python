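import numpy as np
import pytest

from avfppg.synth import (
    AsymmetryParams,
    JitterParams,
    generate_cohort,
    generate_subject,
)


@pytest.fixture(scope="session")
def clean_record():
    """Jitter-free mid-severity record with ground-truth annotations."""
    rec, meta = generate_subject(0.3, duration=10.0, seed=5, jitter=JitterParams.off())
    return rec, meta


@pytest.fixture(scope="session")
def delay_only_record():
    """Pure 50 ms inter-arm foot delay, all other asymmetries off."""
    rec, _ = generate_subject(
        0.0,
        duration=10.0,
        seed=1,
        jitter=JitterParams.off(),
        asymmetry=AsymmetryParams(foot_delay=0.050),
    )
    return rec


@pytest.fixture(scope="session")
def amplitude_only_record():
    """Pure right/left amplitude ratio 0.6, timing symmetric."""
    rec, _ = generate_subject(
        0.0,
        duration=10.0,
        seed=1,
        jitter=JitterParams.off(),
        asymmetry=AsymmetryParams(amplitude_ratio=0.6),
    )
    return rec


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects per class with default jitter; fast enough for CV tests."""
    return generate_cohort(6, seed=11)


@pytest.fixture(scope="session")
def blob_features():
    """Well-separated 3-class Gaussian blobs in 4-D feature space."""
    rng = np.random.default_rng(42)
    centers = np.array(
        [
            [0.1, 0.1, 0.1, 0.1],
            [0.5, 0.5, 0.5, 0.5],
            [0.9, 0.9, 0.9, 0.9],
        ]
    )
    X, y = [], []
    for c in range(3):
        X.append(centers[c] + 0.03 * rng.standard_normal((15, 4)))
        y.extend([c + 1] * 15)
    return np.vstack(X), np.asarray(y)
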