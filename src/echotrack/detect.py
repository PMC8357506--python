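"""Keypoint detection: DoG extrema, subpixel refinement, contrast and edge
rejection, orientation assignment.

The pipeline mirrors the classic scale-invariant feature transform: 3-D
extrema of the DoG stack are refined by fitting a quadratic to the local
samples (x_hat = -H^-1 g), low-contrast points are discarded with the
inclusive |D(x_hat)| >= 0.03 gate, edge-like points are discarded with the
curvature-ratio test on the 2-x-2 spatial Hessian, and each survivor receives
one or more orientations from a 36-bin gradient-direction histogram over a
Gaussian-weighted circular window.

All keypoint coordinates are 0-based (row, col) at the base-image scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .scalespace import ScaleSpace, ScaleSpaceConfig, build_dog, build_scale_space

__all__ = [
    "Keypoint",
    "detect_extrema",
    "refine_extremum",
    "refine_keypoint",
    "contrast_filter",
    "edge_filter",
    "assign_orientation",
    "detect_keypoints",
]

logger = logging.getLogger(__name__)

N_ORI_BINS = 36
ORI_PEAK_RATIO = 0.8
ORI_SIGMA_FACTOR = 1.5  # histogram window sigma = 1.5 * octave-relative scale
ORI_RADIUS_FACTOR = 3.0  # window radius = 3 * (1.5 sigma)


@dataclass(frozen=True)
class Keypoint:
    """Refined scale-space feature point at base-image coordinates."""

    row: float
    col: float
    octave: int
    layer: int
    sigma: float          # absolute scale in base-image pixels
    response: float       # refined |D(x_hat)|-comparable value D(x_hat)
    orientation: float = 0.0  # radians
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (drow, dcol, dlayer)

    @property
    def position(self) -> np.ndarray:
        return np.array([self.row, self.col])

    def octave_coords(self) -> tuple[float, float]:
        """(row, col) on the keypoint's own octave grid."""
        return self.row / 2.0**self.octave, self.col / 2.0**self.octave


def detect_extrema(space: ScaleSpace) -> list[tuple[int, int, int, int]]:
    """Integer-grid 26-neighbourhood strict extrema of every DoG octave.

    Returns (octave, layer, row, col) tuples; first/last DoG layers and 1-px
    image borders are excluded, and responses below half the contrast
    threshold are pre-filtered (they could never pass the refined gate).
    """
    if not space.dog:
        raise ValueError("DoG stack not built; call build_dog first")
    prefilter = 0.5 * space.config.contrast_threshold
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    found: list[tuple[int, int, int, int]] = []
    for o, dog in enumerate(space.dog):
        if dog.shape[0] < 3:
            continue
        neigh_max = ndimage.maximum_filter(dog, footprint=footprint, mode="constant",
                                           cval=-np.inf)
        neigh_min = ndimage.minimum_filter(dog, footprint=footprint, mode="constant",
                                           cval=np.inf)
        is_ext = (dog > neigh_max) | (dog < neigh_min)
        is_ext &= np.abs(dog) >= prefilter
        is_ext[0] = is_ext[-1] = False
        is_ext[:, :1, :] = is_ext[:, -1:, :] = False
        is_ext[:, :, :1] = is_ext[:, :, -1:] = False
        for layer, r, c in zip(*np.nonzero(is_ext)):
            found.append((o, int(layer), int(r), int(c)))
    return found


def _grad_hess(dog: np.ndarray, l: int, r: int, c: int):
    """Central-difference gradient and Hessian of D at (layer, row, col)."""
    g = np.array([
        (dog[l, r + 1, c] - dog[l, r - 1, c]) / 2.0,
        (dog[l, r, c + 1] - dog[l, r, c - 1]) / 2.0,
        (dog[l + 1, r, c] - dog[l - 1, r, c]) / 2.0,
    ])
    d = dog[l, r, c]
    drr = dog[l, r + 1, c] - 2 * d + dog[l, r - 1, c]
    dcc = dog[l, r, c + 1] - 2 * d + dog[l, r, c - 1]
    dll = dog[l + 1, r, c] - 2 * d + dog[l - 1, r, c]
    drc = (dog[l, r + 1, c + 1] - dog[l, r + 1, c - 1]
           - dog[l, r - 1, c + 1] + dog[l, r - 1, c - 1]) / 4.0
    drl = (dog[l + 1, r + 1, c] - dog[l + 1, r - 1, c]
           - dog[l - 1, r + 1, c] + dog[l - 1, r - 1, c]) / 4.0
    dcl = (dog[l + 1, r, c + 1] - dog[l + 1, r, c - 1]
           - dog[l - 1, r, c + 1] + dog[l - 1, r, c - 1]) / 4.0
    h = np.array([[drr, drc, drl], [drc, dcc, dcl], [drl, dcl, dll]])
    return g, h


def refine_extremum(
    dog: np.ndarray, layer: int, row: int, col: int, max_moves: int = 5
):
    """Quadratic subpixel refinement of one raw extremum in a DoG stack.

    Solves x_hat = -H^-1 g; if any component exceeds 0.5 the sample point is
    moved to the neighbouring grid point and the fit repeated, at most
    ``max_moves`` times.  Returns (layer, row, col, offset, value) where
    offset = (drow, dcol, dlayer) and value = D + g.x_hat/2, or (None, reason)
    on rejection.
    """
    l, r, c = layer, row, col
    n_l, n_r, n_c = dog.shape
    for _ in range(max_moves + 1):
        if not (1 <= l < n_l - 1 and 1 <= r < n_r - 1 and 1 <= c < n_c - 1):
            return None, "out_of_bounds"
        g, h = _grad_hess(dog, l, r, c)
        try:
            offset_lrc = -np.linalg.solve(h, g)  # (drow, dcol, dlayer) order below
        except np.linalg.LinAlgError:
            return None, "singular_hessian"
        if not np.all(np.isfinite(offset_lrc)) or np.max(np.abs(offset_lrc)) > 1e3:
            return None, "singular_hessian"
        drow, dcol, dlayer = offset_lrc
        if abs(drow) <= 0.5 and abs(dcol) <= 0.5 and abs(dlayer) <= 0.5:
            value = dog[l, r, c] + 0.5 * float(g @ offset_lrc)
            return (l, r, c, (float(drow), float(dcol), float(dlayer)),
                    float(value)), None
        r += int(np.round(np.clip(drow, -1, 1)))
        c += int(np.round(np.clip(dcol, -1, 1)))
        l += int(np.round(np.clip(dlayer, -1, 1)))
    return None, "no_convergence"


def refine_keypoint(space: ScaleSpace, raw: tuple[int, int, int, int]):
    """Refine one raw (octave, layer, row, col) extremum into a Keypoint.

    Returns (Keypoint, None) or (None, reason).
    """
    octave, layer, row, col = raw
    cfg = space.config
    result, reason = refine_extremum(
        space.dog[octave], layer, row, col, max_moves=cfg.max_refine_moves
    )
    if result is None:
        return None, reason
    l, r, c, (drow, dcol, dlayer), value = result
    scale = 2.0**octave
    sigma = cfg.base_sigma * cfg.k ** (l + dlayer) * scale
    kp = Keypoint(
        row=(r + drow) * scale,
        col=(c + dcol) * scale,
        octave=octave,
        layer=l,
        sigma=sigma,
        response=value,
        offset=(drow, dcol, dlayer),
    )
    return kp, None


def contrast_filter(kp: Keypoint, threshold: float, signed: bool = False) -> bool:
    """Keep iff the refined response passes the inclusive contrast gate.

    Default compares |D(x_hat)| >= threshold so DoG minima (dark blobs) count;
    ``signed`` restores the literal one-sided D(x_hat) >= threshold reading.
    """
    value = kp.response if signed else abs(kp.response)
    return value >= threshold


def edge_filter(space: ScaleSpace, kp: Keypoint,
                ratio_threshold: float | None = None) -> bool:
    """Curvature-ratio edge rejection on the 2x2 spatial DoG Hessian.

    Keep iff det(H) > 0 and tr(H)^2 / det(H) < (r+1)^2 / r (strict).
    """
    r_thr = ratio_threshold if ratio_threshold is not None \
        else space.config.edge_ratio_threshold
    dog = space.dog[kp.octave]
    l = kp.layer
    r0, c0 = kp.octave_coords()
    r, c = int(round(r0)), int(round(c0))
    n_r, n_c = dog.shape[1:]
    if not (1 <= r < n_r - 1 and 1 <= c < n_c - 1):
        return False
    d = dog[l, r, c]
    drr = dog[l, r + 1, c] - 2 * d + dog[l, r - 1, c]
    dcc = dog[l, r, c + 1] - 2 * d + dog[l, r, c - 1]
    drc = (dog[l, r + 1, c + 1] - dog[l, r + 1, c - 1]
           - dog[l, r - 1, c + 1] + dog[l, r - 1, c - 1]) / 4.0
    tr = drr + dcc
    det = drr * dcc - drc * drc
    if det <= 0:
        return False
    return bool(tr * tr * r_thr < (r_thr + 1.0) ** 2 * det)


def gradient_angle(d_row: np.ndarray, d_col: np.ndarray,
                   printed_order: bool = True) -> np.ndarray:
    """Gradient direction in radians.

    ``printed_order`` puts the row difference in the numerator —
    atan2(L(x+1,y) - L(x-1,y), L(x,y+1) - L(x,y-1)) — which measures the angle
    of the gradient vector from the +col axis toward +row; the alternative
    swaps the arguments.
    """
    if printed_order:
        return np.arctan2(d_row, d_col)
    return np.arctan2(d_col, d_row)


def assign_orientation(space: ScaleSpace, kp: Keypoint) -> list[Keypoint]:
    """Dominant gradient orientation(s) of the keypoint neighbourhood.

    Accumulates a 36-bin histogram of gradient directions, weighted by
    gradient magnitude and a Gaussian of sigma = 1.5 * scale over a circular
    window of radius 3 * 1.5 * scale; emits the main peak and one extra
    keypoint per secondary peak >= 80% of the maximum, each refined by
    parabolic interpolation over three bins.  Returns [] when the window does
    not fit inside the image.
    """
    cfg = space.config
    li = int(np.clip(round(kp.layer + kp.offset[2]), 0, cfg.layers_per_octave - 1))
    img = space.gaussians[kp.octave][li]
    sigma_oct = space.octave_sigma(kp.octave, kp.layer + kp.offset[2])
    win_sigma = ORI_SIGMA_FACTOR * sigma_oct
    radius = max(1, int(round(ORI_RADIUS_FACTOR * win_sigma)))
    r0, c0 = kp.octave_coords()
    r, c = int(round(r0)), int(round(c0))
    if (r - radius < 1 or r + radius > img.shape[0] - 2
            or c - radius < 1 or c + radius > img.shape[1] - 2):
        return []
    patch = img[r - radius - 1:r + radius + 2, c - radius - 1:c + radius + 2]
    d_row = patch[2:, 1:-1] - patch[:-2, 1:-1]
    d_col = patch[1:-1, 2:] - patch[1:-1, :-2]
    mag = np.hypot(d_row, d_col)
    ang = gradient_angle(d_row, d_col, cfg.printed_atan2)
    ax = np.arange(-radius, radius + 1, dtype=float)
    rr, cc = np.meshgrid(ax, ax, indexing="ij")
    weight = np.exp(-(rr**2 + cc**2) / (2.0 * win_sigma**2))
    weight[rr**2 + cc**2 > radius**2] = 0.0  # circular window

    w = mag * weight
    if not np.any(w > 0):
        logger.warning("all-zero gradients at keypoint (%.1f, %.1f)", kp.row, kp.col)
        return [replace(kp, orientation=0.0)]
    bins = np.round(ang / (2 * np.pi / N_ORI_BINS)).astype(int) % N_ORI_BINS
    hist = np.zeros(N_ORI_BINS)
    np.add.at(hist, bins.ravel(), w.ravel())

    peak = hist.max()
    out: list[Keypoint] = []
    for i in range(N_ORI_BINS):
        left, right = hist[(i - 1) % N_ORI_BINS], hist[(i + 1) % N_ORI_BINS]
        if hist[i] >= ORI_PEAK_RATIO * peak and hist[i] > left and hist[i] > right:
            denom = left - 2 * hist[i] + right
            interp = 0.0 if denom == 0 else 0.5 * (left - right) / denom
            theta = (i + interp) * (2 * np.pi / N_ORI_BINS)
            theta = float(np.mod(theta + np.pi, 2 * np.pi) - np.pi)
            out.append(replace(kp, orientation=theta))
    # main peak first for determinism
    out.sort(key=lambda q: -hist[int(round(q.orientation / (2 * np.pi / N_ORI_BINS)))
                                 % N_ORI_BINS])
    return out


def detect_keypoints(
    frame: np.ndarray,
    cfg: ScaleSpaceConfig | None = None,
    space: ScaleSpace | None = None,
) -> list[Keypoint]:
    """Full detection chain on one frame.

    Builds (or reuses) the scale space, finds and refines DoG extrema, applies
    the contrast and edge gates and assigns orientations.  Returns oriented
    keypoints at base-image coordinates.
    """
    cfg = cfg or ScaleSpaceConfig()
    if space is None:
        space = build_dog(build_scale_space(frame, cfg))
    elif not space.dog:
        build_dog(space)
    keypoints: list[Keypoint] = []
    rejections = {"refine": 0, "contrast": 0, "edge": 0, "window": 0}
    for raw in detect_extrema(space):
        kp, _ = refine_keypoint(space, raw)
        if kp is None:
            rejections["refine"] += 1
            continue
        if not contrast_filter(kp, cfg.contrast_threshold, cfg.signed_contrast):
            rejections["contrast"] += 1
            continue
        if not edge_filter(space, kp):
            rejections["edge"] += 1
            continue
        oriented = assign_orientation(space, kp)
        if not oriented:
            rejections["window"] += 1
            continue
        keypoints.extend(oriented)
    logger.info(
        "detected %d keypoints (rejected: %s)", len(keypoints), rejections
    )
    return keypoints
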