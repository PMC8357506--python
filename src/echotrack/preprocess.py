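"""Despeckling by weighted neighbourhood-mean filtering.

Ultrasound frames carry isolated bright/dark noise pixels (salt-and-pepper,
impulse) on top of the speckle texture.  A linear mean filter — each output
pixel the weighted average of an m x n neighbourhood — suppresses those
before feature extraction.  The default is the plain 3 x 3 average; arbitrary
odd-sized masks and non-uniform weights are accepted, the weights being
normalised to sum to one so constants are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MeanFilterSpec", "mean_filter", "to_grayscale"]

# Rec. 601 luma weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class MeanFilterSpec:
    """m x n averaging mask; ``weights`` None means uniform."""

    rows: int = 3
    cols: int = 3
    weights: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.rows % 2 == 0 or self.cols % 2 == 0:
            raise ValueError("mask dimensions must be odd and >= 1")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.rows, self.cols):
                raise ValueError("weights shape must match (rows, cols)")
            if w.sum() <= 0:
                raise ValueError("weights must have a positive sum")

    def kernel(self) -> np.ndarray:
        """Mask normalised to sum 1."""
        if self.weights is None:
            return np.full((self.rows, self.cols), 1.0 / (self.rows * self.cols))
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()


def mean_filter(frame: np.ndarray, spec: MeanFilterSpec | None = None) -> np.ndarray:
    """Weighted neighbourhood average; borders handled by edge replication."""
    spec = spec or MeanFilterSpec()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a nonempty 2-D array")
    if spec.rows > frame.shape[0] or spec.cols > frame.shape[1]:
        raise ValueError("mask must be smaller than the frame")
    return ndimage.correlate(frame, spec.kernel(), mode="nearest")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) image to gray with Rec. 601 luma weights."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] >= 3:
        return image[..., :3] @ _LUMA
    raise ValueError("expected a 2-D gray or 3-D RGB(A) image")
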