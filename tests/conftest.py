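import numpy as np
import pytest

from pigparts.core import FrameAnnotation, PigAnnotation, Point2D
from pigparts.scenes import make_pig


@pytest.fixture
def single_pig_frame() -> FrameAnnotation:
    """One pig, axis-aligned, integer keypoints (easy to reason about)."""
    return FrameAnnotation(
        image_size=(200, 300),
        pigs=[PigAnnotation(shoulder=Point2D(150.0, 100.0), tail=Point2D(80.0, 100.0),
                            left_ear=Point2D(178.0, 82.0), right_ear=Point2D(178.0, 118.0),
                            instance_id=0)],
    )


@pytest.fixture
def two_pig_frame() -> FrameAnnotation:
    """Two well-separated pigs with different sizes."""
    return FrameAnnotation(
        image_size=(320, 420),
        pigs=[make_pig(np.array([110.0, 100.0]), 0.3, 80.0, 0),
              make_pig(np.array([290.0, 230.0]), 2.1, 60.0, 1)],
    )


@pytest.fixture
def central_frame() -> FrameAnnotation:
    """Pigs clustered near the center so any augmentation keeps them inside."""
    return FrameAnnotation(
        image_size=(320, 320),
        pigs=[make_pig(np.array([130.0, 160.0]), 0.7, 42.0, 0),
              make_pig(np.array([190.0, 140.0]), 3.5, 38.0, 1),
              make_pig(np.array([160.0, 200.0]), 5.1, 36.0, 2)],
    )
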