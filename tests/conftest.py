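import numpy as np
import pytest

from coilpose.evaluation import build_references
from coilpose.fixtures import FixtureWorld, fixture_shape_corpus, generate_fixture_video
from coilpose.shape_model import fit_shape_model


@pytest.fixture(scope="session")
def world():
    return FixtureWorld(duration_s=10.0, seed=3)


@pytest.fixture(scope="session")
def video(world):
    return generate_fixture_video(world)


@pytest.fixture(scope="session")
def references(video):
    refs = build_references(video, image_size=48, n_skeleton_points=33, n_references=20)
    assert len(refs) >= 10
    return refs


@pytest.fixture(scope="session")
def corpus(world):
    shapes, basis = fixture_shape_corpus(world, n=2000, seed=11)
    return shapes, basis


@pytest.fixture(scope="session")
def small_shape_model(corpus):
    shapes, _ = corpus
    return fit_shape_model(shapes, n_components=20, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
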