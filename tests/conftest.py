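import numpy as np
import pytest

from aefn import AnnotationMatrix, FeatureMatrix, MISSING


@pytest.fixture
def tiny_annotations():
    """3 instances × 2 annotators, fully observed."""
    return AnnotationMatrix(
        np.array([[1, 0], [0, 0], [1, 1]]),
        ("i1", "i2", "i3"), ("annA", "annB"))


@pytest.fixture
def tiny_features():
    return FeatureMatrix(
        np.array([[0.5, -1.0], [1.5, 2.0], [-0.25, 0.0]]),
        ("f1", "f2"), ("i1", "i2", "i3"))


def random_annotations(rng, n, r, missing_rate=0.0):
    """Random observed-label grid keeping the >=1-observed invariant."""
    labels = rng.integers(0, 2, size=(n, r))
    if missing_rate > 0:
        mask = rng.random((n, r)) < missing_rate
        dead = mask.all(axis=1)
        mask[np.flatnonzero(dead), rng.integers(0, r, size=int(dead.sum()))] = False
        labels = np.where(mask, MISSING, labels)
    return AnnotationMatrix(labels, tuple(f"i{i}" for i in range(n)),
                            tuple(f"a{j}" for j in range(r)))
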