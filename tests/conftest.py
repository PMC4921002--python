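import math

import numpy as np
import pytest

CLUSTER_MEANS = np.array([[1800.0, 200.0], [1000.0, 1000.0], [200.0, 1800.0]])
# adjacent-cluster mean distance for the default (contrast 0.8, total 2000) geometry
CLUSTER_DISTANCE = 0.8 * 2000.0 / math.sqrt(2.0)


def noise_sd_for_separation(sep_sigma: float) -> float:
    """Per-channel noise sd giving the requested cluster separation (in sd units)."""
    return CLUSTER_DISTANCE / sep_sigma


def three_cluster_data(
    counts=(200, 200, 200), sep_sigma=6.0, seed=0, clip=True
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian intensity clusters at the AA/AB/BB positions; returns (X, labels)."""
    rng = np.random.default_rng(seed)
    sd = noise_sd_for_separation(sep_sigma)
    parts, labels = [], []
    for k, c in enumerate(counts):
        if c == 0:
            continue
        parts.append(CLUSTER_MEANS[k] + rng.normal(scale=sd, size=(c, 2)))
        labels.extend([k] * c)
    X = np.vstack(parts)
    if clip:
        np.clip(X, 0.0, None, out=X)
    return X, np.asarray(labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
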