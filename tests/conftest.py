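import numpy as np
import pytest

from vertasm import ActiveShapeModel, SyntheticSpec, generate_training_set
from vertasm.shapes import Shape, TrainingSet, default_marking


UNIT_SQUARE = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def square_shape():
    """Axis-aligned unit square marked with 8 landmarks (mid-edge points)."""
    return default_marking(UNIT_SQUARE * 10 + 5, 8)


@pytest.fixture(scope="session")
def small_training_set(rng):
    """20 single-vertebra shapes: a quadrilateral with 2 generative modes."""
    shapes = []
    base = default_marking(UNIT_SQUARE * np.array([30, 40]) + 20, 20)
    for _ in range(20):
        a = rng.normal(0, 0.05)
        s = rng.normal(0, 0.04)
        pts = base.points.copy()
        c = pts.mean(axis=0)
        pts = pts - c
        pts[:, 0] *= 1 + a
        pts[:, 1] *= 1 - a
        pts[:, 0] += s * pts[:, 1]
        shapes.append(Shape(pts + c, 1, 20))
    return TrainingSet(shapes)


@pytest.fixture(scope="session")
def synthetic_spine():
    from vertasm.synthetic import generate_spine

    return generate_spine(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def trained_estimator():
    """Vertebra-model estimator trained on 25 phantoms (shared across tests)."""
    spec = SyntheticSpec(seed=5)
    _, spines = generate_training_set(spec, 25)
    est = ActiveShapeModel()
    est.fit([s.image for s in spines], [s.shape for s in spines])
    return est, spines
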