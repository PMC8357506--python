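"""128-dimensional rotation-invariant gradient descriptors.

Gradients are sampled from the keypoint's Gaussian layer inside a circular
window of radius R = ceil((3 sigma sqrt(2) (d+1) + 1) / 2); sample offsets are
rotated by minus the keypoint orientation so the histogram grid is aligned
with the dominant gradient direction, then accumulated into a d x d grid of
8-bin orientation histograms with trilinear interpolation and a spatial
Gaussian weight.  Entries are clamped (illumination robustness) and the
vector renormalised — by Euclidean norm by default, or by the plain sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt

import numpy as np

from .detect import Keypoint, gradient_angle
from .scalespace import ScaleSpace

__all__ = [
    "DescriptorConfig",
    "descriptor_radius",
    "rotate_coords",
    "normalize_descriptor",
    "compute_descriptor",
    "compute_descriptors",
]


@dataclass(frozen=True)
class DescriptorConfig:
    grid: int = 4                 # d subregions per side
    bins: int = 8                 # orientation bins per subregion
    clamp_value: float | None = 0.2
    normalization_mode: str = "euclidean"  # or "sum"
    sigma_weighting: float = 0.5  # Gaussian sigma as a fraction of window width

    def __post_init__(self) -> None:
        if self.grid < 1 or self.bins < 1:
            raise ValueError("grid and bins must be >= 1")
        if self.normalization_mode not in ("euclidean", "sum"):
            raise ValueError("normalization_mode must be 'euclidean' or 'sum'")
        if self.clamp_value is not None and self.clamp_value <= 0:
            raise ValueError("clamp_value must be positive or None")

    @property
    def length(self) -> int:
        return self.grid * self.grid * self.bins


def descriptor_radius(sigma: float, d: int = 4) -> int:
    """Window radius R = ceil((3 sigma sqrt(2) (d + 1) + 1) / 2) in pixels."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if d < 1:
        raise ValueError("grid size d must be >= 1")
    return ceil((3.0 * sigma * sqrt(2.0) * (d + 1) + 1.0) / 2.0)


def rotate_coords(offset, alpha: float):
    """Rotate (d_row, d_col) offsets by ``alpha`` radians.

    Angles are measured from the +col axis toward the +row axis, matching the
    gradient-angle convention, so rotating a patch and its coordinates by the
    same alpha leaves descriptors unchanged.
    """
    drow, dcol = np.asarray(offset[0], float), np.asarray(offset[1], float)
    c, s = np.cos(alpha), np.sin(alpha)
    return s * dcol + c * drow, c * dcol - s * drow


def normalize_descriptor(raw: np.ndarray, mode: str = "euclidean") -> np.ndarray:
    """Normalise to unit Euclidean norm or unit sum; all-zero input is an error."""
    raw = np.asarray(raw, dtype=float)
    if mode == "sum":
        total = raw.sum()
    elif mode == "euclidean":
        total = np.linalg.norm(raw)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if total <= 0:
        raise ValueError("cannot normalize an all-zero descriptor")
    return raw / total


def compute_descriptor(
    space: ScaleSpace, kp: Keypoint, cfg: DescriptorConfig | None = None
) -> np.ndarray | None:
    """Descriptor of one oriented keypoint, or None when the window exits the
    image or the patch has no gradient energy."""
    cfg = cfg or DescriptorConfig()
    scfg = space.config
    d = cfg.grid
    li = int(np.clip(round(kp.layer + kp.offset[2]), 0, scfg.layers_per_octave - 1))
    img = space.gaussians[kp.octave][li]
    sigma_oct = space.octave_sigma(kp.octave, kp.layer + kp.offset[2])
    subwidth = 3.0 * sigma_oct           # histogram subregion width in pixels
    radius = descriptor_radius(sigma_oct, d)
    r_ctr, c_ctr = kp.octave_coords()
    r0, c0 = int(round(r_ctr)), int(round(c_ctr))
    if (r0 - radius < 1 or r0 + radius > img.shape[0] - 2
            or c0 - radius < 1 or c0 + radius > img.shape[1] - 2):
        return None

    patch = img[r0 - radius - 1:r0 + radius + 2, c0 - radius - 1:c0 + radius + 2]
    g_row = patch[2:, 1:-1] - patch[:-2, 1:-1]
    g_col = patch[1:-1, 2:] - patch[1:-1, :-2]
    mag = np.hypot(g_row, g_col)
    ang = gradient_angle(g_row, g_col, scfg.printed_atan2)

    ax = np.arange(-radius, radius + 1, dtype=float)
    drow, dcol = np.meshgrid(ax + (r0 - r_ctr), ax + (c0 - c_ctr), indexing="ij")
    inside = drow**2 + dcol**2 <= radius**2  # circular sampling region
    rot_r, rot_c = rotate_coords((drow, dcol), -kp.orientation)

    # histogram-grid coordinates: subregion centres at 0 .. d-1
    v = rot_r / subwidth + d / 2.0 - 0.5
    u = rot_c / subwidth + d / 2.0 - 0.5
    win_sigma = cfg.sigma_weighting * d * subwidth
    weight = np.exp(-(rot_r**2 + rot_c**2) / (2.0 * win_sigma**2))
    rel_ang = np.mod(ang - kp.orientation, 2.0 * np.pi)
    obin = rel_ang / (2.0 * np.pi / cfg.bins)

    keep = inside & (v > -1) & (v < d) & (u > -1) & (u < d) & (mag > 0)
    if not np.any(keep):
        return None
    v, u, ob = v[keep], u[keep], obin[keep]
    w = (mag * weight)[keep]

    hist = np.zeros((d, d, cfg.bins))
    v0, u0, o0 = np.floor(v).astype(int), np.floor(u).astype(int), np.floor(ob).astype(int)
    fv, fu, fo = v - v0, u - u0, ob - o0
    for dv in (0, 1):
        wv = np.where(dv == 0, 1 - fv, fv)
        iv = v0 + dv
        for du in (0, 1):
            wu = np.where(du == 0, 1 - fu, fu)
            iu = u0 + du
            for do in (0, 1):
                wo = np.where(do == 0, 1 - fo, fo)
                io = (o0 + do) % cfg.bins
                ok = (iv >= 0) & (iv < d) & (iu >= 0) & (iu < d)
                np.add.at(
                    hist,
                    (iv[ok], iu[ok], io[ok]),
                    (w * wv * wu * wo)[ok],
                )
    vec = hist.ravel()
    if vec.sum() <= 0:
        return None
    vec = normalize_descriptor(vec, cfg.normalization_mode)
    if cfg.clamp_value is not None:
        vec = np.minimum(vec, cfg.clamp_value)
        vec = normalize_descriptor(vec, cfg.normalization_mode)
    return vec


def compute_descriptors(
    space: ScaleSpace,
    keypoints: list[Keypoint],
    cfg: DescriptorConfig | None = None,
):
    """Describe many keypoints; returns (n, 128) array + the kept keypoints."""
    cfg = cfg or DescriptorConfig()
    vecs, kept = [], []
    for kp in keypoints:
        vec = compute_descriptor(space, kp, cfg)
        if vec is not None:
            vecs.append(vec)
            kept.append(kp)
    if not vecs:
        return np.empty((0, cfg.length)), []
    return np.vstack(vecs), kept
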