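import numpy as np
import pytest

from capsulezone.annotations_io import InterfaceSegment, SlideAnnotationSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_slide(segments_spec, slide_id="s1", **kwargs):
    """Build a SlideAnnotationSet from (vertices, pattern) pairs."""
    segments = [
        InterfaceSegment(np.asarray(v, dtype=float), pattern, slide_id)
        for v, pattern in segments_spec
    ]
    return SlideAnnotationSet(slide_id=slide_id, interface_segments=segments, **kwargs)


def random_polyline(rng, n_vertices=10, scale=100.0):
    """Random polyline with distinct consecutive vertices."""
    steps = rng.uniform(0.5, 2.0, size=(n_vertices - 1, 2)) * rng.choice(
        [-1.0, 1.0], size=(n_vertices - 1, 2)
    )
    return np.vstack([[0.0, 0.0], np.cumsum(steps * scale, axis=0)])


@pytest.fixture
def random_labeled_slide(rng):
    """Slide with 10 random polylines labeled with random patterns."""
    patterns = rng.choice(["encapsulated", "replacement", "pushing"], size=10)
    spec = [(random_polyline(rng), p) for p in patterns]
    return make_slide(spec), spec
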