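import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import varcal as vc

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240222)


@pytest.fixture
def small_binary():
    """Ten items, mixed labels, a tie at score 0.4."""
    return vc.LabeledScores(
        item_ids=[f"v{i}" for i in range(10)],
        scores=[0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.4, 0.3, 0.2, 0.1],
        labels=[1, 1, 1, 0, 1, 0, 1, 0, 0, 0],
    )


@pytest.fixture
def binormal_10k():
    scores, truth = vc.generate_binary(vc.BinormalSpec(n=10_000, seed=42))
    return scores, truth


def random_labeled_scores(rng, n, tie_prob=0.5):
    """Random instance with ties injected, both classes guaranteed."""
    if rng.random() < tie_prob:
        scores = rng.integers(0, max(2, n // 3), size=n).astype(float)
    else:
        scores = rng.normal(size=n)
    labels = rng.integers(0, 2, size=n)
    labels[0], labels[1] = 0, 1
    ids = [f"v{i}" for i in range(n)]
    return vc.LabeledScores(ids, scores, labels)
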