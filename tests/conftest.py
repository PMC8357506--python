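import logging

import numpy as np
import pytest

import echotrack as et
from echotrack.descriptor import compute_descriptors
from echotrack.detect import detect_keypoints
from echotrack.scalespace import build_dog, build_scale_space

logging.getLogger("echotrack").setLevel(logging.ERROR)


@pytest.fixture
def speckle_frame():
    """Factory for deterministic speckle phantoms."""

    def _make(seed=0, size=128, density=0.08, blur=1.5):
        spec = et.PhantomSpec(height=size, width=size, speckle_density=density,
                              blur_sigma=blur, seed=seed)
        return et.make_speckle_frame(spec)

    return _make


@pytest.fixture
def features():
    """Factory: frame -> (scale space, oriented keypoints, descriptor array)."""

    def _extract(frame, scale_cfg=None, desc_cfg=None):
        space = build_dog(build_scale_space(frame, scale_cfg))
        kps = detect_keypoints(frame, scale_cfg, space=space)
        descs, kept = compute_descriptors(space, kps, desc_cfg)
        return space, kept, descs

    return _extract


def shift_field(shape, drow, dcol):
    """Constant displacement field helper used across test modules."""
    field = np.empty((2, *shape))
    field[0] = drow
    field[1] = dcol
    return field
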