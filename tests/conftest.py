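import numpy as np
import pytest

from growthmap.classes import GrowthPattern
from growthmap.slide_io import SlideImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_slide(width, height, fill=255, pixel_size_um=0.5):
    """A uniform single-color slide with a synthesized coarse level."""
    level0 = np.full((height, width, 3), fill, dtype=np.uint8)
    from growthmap.slide_io import _synthesized_levels

    levels, downs = _synthesized_levels(level0, 10.0 / pixel_size_um)
    return SlideImage(levels, downs, pixel_size_um, 10.0 / pixel_size_um, slide_id="fixture")


@pytest.fixture
def white_slide():
    return make_slide(1200, 600)


def random_prob_vectors(rng, n):
    """Valid random 5-class probability vectors."""
    raw = rng.dirichlet(np.ones(5), size=n)
    return raw


@pytest.fixture
def square_annotation():
    from growthmap.slide_io import AnnotationRegion, AnnotationSet

    square = np.array([(5.0, 5.0), (15.0, 5.0), (15.0, 15.0), (5.0, 15.0)])
    return AnnotationSet([AnnotationRegion(square, GrowthPattern.AC)])
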