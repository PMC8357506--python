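"""Synthetic speckle phantoms with known ground-truth motion.

Real echocardiographic cine loops are dominated by speckle: granular
interference texture produced by sub-resolution scatterers.  The phantom
emulates that texture as a random field of bright point scatterers smoothed
by a Gaussian point-spread function, deformed frame to frame by an analytic
motion model (translation, rotation about a centre, or a periodic radial
"cardiac" contraction), and optionally corrupted by additive Gaussian,
salt-and-pepper or multiplicative speckle noise.  Because the motion model is
analytic, every frame carries an exact ground-truth displacement field, which
is what makes the detector, matcher, flow estimator and tracker testable
without clinical recordings.

Conventions
-----------
* Frames are 2-D float arrays with intensities in [0, 1], indexed [row, col].
* Dense displacement fields are arrays of shape (2, H, W) holding (d_row,
  d_col) in pixels, cumulative relative to frame 0.  ``warp_frame`` treats the
  field as the forward motion of the content: the output at pixel x is the
  input sampled at x - d(x), so a constant field (2, 0) moves the image down
  by two rows.
* Forward point motion is exposed separately via
  :meth:`MotionModel.transform_points` so seed points can be propagated
  exactly for trajectory ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "MotionModel",
    "Translation",
    "Rotation",
    "PeriodicRadial",
    "PhantomSequence",
    "scatterer_field",
    "make_speckle_frame",
    "warp_frame",
    "add_noise",
    "make_sequence",
]

NOISE_KINDS = ("none", "gaussian", "salt_pepper", "speckle")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one speckle phantom.

    speckle_density is the per-pixel probability of a bright scatterer before
    point-spread smoothing; blur_sigma is the PSF width in pixels.  Identical
    seeds give bit-identical phantoms.
    """

    height: int = 128
    width: int = 128
    speckle_density: float = 0.08
    blur_sigma: float = 1.5
    noise_kind: str = "none"
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom dimensions must be >= 32 pixels")
        if not 0.0 <= self.speckle_density < 1.0:
            raise ValueError("speckle_density must lie in [0, 1)")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.noise_kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.noise_kind!r}")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


def scatterer_field(spec: PhantomSpec) -> np.ndarray:
    """Pre-blur scatterer image: bright points of random amplitude on zeros."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    mask = rng.random((spec.height, spec.width)) < spec.speckle_density
    amplitude = rng.uniform(0.5, 1.0, size=(spec.height, spec.width))
    return np.where(mask, amplitude, 0.0)


def make_speckle_frame(spec: PhantomSpec) -> np.ndarray:
    """Speckle frame in [0, 1]: scatterers smoothed by the PSF.

    Intensity is standardised by the 99.9th percentile rather than the peak
    (a single bright scatterer cluster must not compress the contrast of the
    whole frame) and clipped to [0, 1].
    """
    frame = scatterer_field(spec)
    if spec.blur_sigma > 0:
        frame = ndimage.gaussian_filter(frame, spec.blur_sigma, mode="nearest")
    scale = np.percentile(frame, 99.9)
    if scale > 0:
        frame = np.clip(frame / scale, 0.0, 1.0)
    return frame


def warp_frame(
    frame: np.ndarray,
    displacement: np.ndarray,
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Resample ``frame`` under a dense (2, H, W) displacement field.

    Output pixel x takes the value of the input at x - d(x); out-of-frame
    samples are filled by edge replication.
    """
    frame = np.asarray(frame, dtype=float)
    displacement = np.asarray(displacement, dtype=float)
    if displacement.shape != (2, *frame.shape):
        raise ValueError(
            f"displacement shape {displacement.shape} does not match frame "
            f"{frame.shape}"
        )
    orders = {"nearest": 0, "bilinear": 1, "bicubic": 3}
    if interpolation not in orders:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    rows, cols = np.meshgrid(
        np.arange(frame.shape[0]), np.arange(frame.shape[1]), indexing="ij"
    )
    coords = np.stack([rows - displacement[0], cols - displacement[1]])
    out = ndimage.map_coordinates(
        frame, coords, order=orders[interpolation], mode="nearest"
    )
    if interpolation == "bicubic":
        out = np.clip(out, frame.min(), frame.max())  # tame spline overshoot
    return out


def add_noise(frame: np.ndarray, kind: str, level: float, seed: int) -> np.ndarray:
    """Apply the named noise model and clip to [0, 1]; deterministic in seed."""
    if kind not in NOISE_KINDS:
        raise ValueError(f"unknown noise kind {kind!r}")
    if level < 0:
        raise ValueError("noise level must be >= 0")
    frame = np.asarray(frame, dtype=float)
    if kind == "none" or level == 0:
        return frame.copy()
    rng = np.random.default_rng(seed)
    if kind == "gaussian":
        out = frame + rng.normal(0.0, level, size=frame.shape)
    elif kind == "salt_pepper":
        corrupt = rng.random(frame.shape) < level
        salt = rng.random(frame.shape) < 0.5
        out = frame.copy()
        out[corrupt & salt] = 1.0
        out[corrupt & ~salt] = 0.0
    else:  # speckle: multiplicative
        out = frame * (1.0 + level * rng.normal(0.0, 1.0, size=frame.shape))
    return np.clip(out, 0.0, 1.0)


class MotionModel:
    """Analytic frame-to-frame motion with exact ground truth.

    Subclasses provide the cumulative (frame-0-referenced) motion at integer
    frame index t, both as a dense pull-back displacement field for warping
    and as a forward map of individual points.
    """

    def displacement_field(self, shape: tuple[int, int], t: int) -> np.ndarray:
        """Dense (2, H, W) field d with frame_t(x) = frame_0(x - d(x))."""
        raise NotImplementedError

    def transform_points(self, points: np.ndarray, shape: tuple[int, int], t: int) -> np.ndarray:
        """Forward-map (n, 2) frame-0 (row, col) points to their frame-t positions."""
        raise NotImplementedError

    def _center(self, shape: tuple[int, int]) -> np.ndarray:
        return np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])


@dataclass(frozen=True)
class Translation(MotionModel):
    """Uniform translation by ``velocity`` = (d_row, d_col) pixels per frame."""

    velocity: tuple[float, float] = (1.0, 0.0)

    def displacement_field(self, shape, t):
        d = np.empty((2, *shape))
        d[0] = self.velocity[0] * t
        d[1] = self.velocity[1] * t
        return d

    def transform_points(self, points, shape, t):
        return np.asarray(points, dtype=float) + np.asarray(self.velocity) * t


def _rotate_offsets(drow: np.ndarray, dcol: np.ndarray, angle: float):
    """Rotate (row, col) offsets by ``angle`` radians, +col axis toward +row."""
    c, s = np.cos(angle), np.sin(angle)
    return s * dcol + c * drow, c * dcol - s * drow


@dataclass(frozen=True)
class Rotation(MotionModel):
    """Rigid rotation by ``degrees_per_frame`` about ``center`` (image centre
    when None)."""

    degrees_per_frame: float = 1.0
    center: tuple[float, float] | None = None

    def _angle(self, t: int) -> float:
        return np.deg2rad(self.degrees_per_frame * t)

    def displacement_field(self, shape, t):
        center = np.asarray(self.center, float) if self.center else self._center(shape)
        rows, cols = np.meshgrid(
            np.arange(shape[0], dtype=float), np.arange(shape[1], dtype=float),
            indexing="ij",
        )
        drow, dcol = rows - center[0], cols - center[1]
        # pull-back: the content now at x started at c + R(-theta)(x - c)
        r0, c0 = _rotate_offsets(drow, dcol, -self._angle(t))
        return np.stack([drow - r0, dcol - c0])

    def transform_points(self, points, shape, t):
        points = np.asarray(points, dtype=float)
        center = np.asarray(self.center, float) if self.center else self._center(shape)
        dr, dc = points[..., 0] - center[0], points[..., 1] - center[1]
        rr, rc = _rotate_offsets(dr, dc, self._angle(t))
        return np.stack([center[0] + rr, center[1] + rc], axis=-1)


@dataclass(frozen=True)
class PeriodicRadial(MotionModel):
    """Periodic radial contraction emulating a cardiac cycle.

    A point at the reference radius moves inward by s(t) = amplitude *
    sin^2(pi t / period) pixels: zero displacement at end-diastole (t = 0 and
    t = period), peak contraction at mid-cycle t = period / 2.  Displacement
    scales linearly with distance from the centre so the deformation is a pure
    scaling and remains invertible.
    """

    amplitude: float = 3.0
    period: int = 20
    center: tuple[float, float] | None = None
    reference_radius: float | None = None

    def _scale(self, shape: tuple[int, int], t: int) -> float:
        r0 = self.reference_radius or min(shape) / 2.0
        s = self.amplitude * np.sin(np.pi * t / self.period) ** 2
        lam = 1.0 - s / r0
        if lam <= 0:
            raise ValueError("contraction amplitude collapses the phantom")
        return lam

    def displacement_field(self, shape, t):
        lam = self._scale(shape, t)
        center = np.asarray(self.center, float) if self.center else self._center(shape)
        rows, cols = np.meshgrid(
            np.arange(shape[0], dtype=float), np.arange(shape[1], dtype=float),
            indexing="ij",
        )
        drow, dcol = rows - center[0], cols - center[1]
        factor = 1.0 - 1.0 / lam
        return np.stack([drow * factor, dcol * factor])

    def transform_points(self, points, shape, t):
        points = np.asarray(points, dtype=float)
        lam = self._scale(shape, t)
        center = np.asarray(self.center, float) if self.center else self._center(shape)
        return center + lam * (points - center)


@dataclass
class PhantomSequence:
    """Frames plus exact ground truth for one simulated cine loop."""

    frames: list[np.ndarray]
    fields: list[np.ndarray]  # cumulative (2, H, W) displacement per frame
    spec: PhantomSpec
    motion: MotionModel

    def __len__(self) -> int:
        return len(self.frames)

    def true_positions(self, points: Sequence[Sequence[float]], t: int) -> np.ndarray:
        return self.motion.transform_points(np.asarray(points, float),
                                            self.frames[0].shape, t)


def make_sequence(
    spec: PhantomSpec, motion: MotionModel, n_frames: int
) -> PhantomSequence:
    """Simulate a cine loop: frame t = noise(warp(frame_0, field_t))."""
    if n_frames < 2:
        raise ValueError("a sequence needs at least 2 frames")
    base = make_speckle_frame(spec)
    noise_seeds = np.random.SeedSequence([spec.seed, 1]).generate_state(n_frames)
    frames, fields = [], []
    for t in range(n_frames):
        field_t = motion.displacement_field(base.shape, t)
        frame_t = base if t == 0 else warp_frame(base, field_t)
        frame_t = add_noise(
            frame_t, spec.noise_kind, spec.noise_level, int(noise_seeds[t])
        )
        frames.append(frame_t)
        fields.append(field_t)
    return PhantomSequence(frames=frames, fields=fields, spec=spec, motion=motion)
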