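"""Gaussian scale space and difference-of-Gaussians stack.

The detector searches for blob-like speckle features across scale.  Each
octave holds s + 3 Gaussian-smoothed layers L(x, y, sigma) at sigma =
base_sigma * k^i (k = 2^(1/s)) relative to the octave's sampling, so that
adjacent-layer differences give s + 2 DoG layers and the middle s layers can
be searched for 3-D extrema.  The next octave is seeded by 2x decimation of
the layer at 2 * base_sigma, halving linear resolution.

The input frame is assumed to carry a small pre-existing blur
(``assumed_blur``, a camera/scan-conversion prior); the first layer is
smoothed by the quadrature difference so its absolute scale is exactly
base_sigma.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special

__all__ = [
    "ScaleSpaceConfig",
    "ScaleSpace",
    "gaussian_kernel_2d",
    "discrete_gaussian_kernel_1d",
    "smooth",
    "build_scale_space",
    "build_dog",
]

logger = logging.getLogger(__name__)

_MIN_OCTAVE_SIZE = 16  # smallest linear dimension worth an octave


@dataclass(frozen=True)
class ScaleSpaceConfig:
    """Detector-side parameters.

    contrast_threshold gates the refined DoG response |D(x_hat)| >= 0.03;
    edge_ratio_threshold r rejects edge-like points whose spatial-Hessian
    curvature ratio fails tr(H)^2/det(H) < (r+1)^2/r.
    """

    base_sigma: float = 1.6
    scales_per_octave: int = 3
    octave_count: int | None = None
    contrast_threshold: float = 0.03
    edge_ratio_threshold: float = 10.0
    assumed_blur: float = 0.5
    signed_contrast: bool = False      # literal reading: keep only D(x_hat) >= thresh
    printed_atan2: bool = True         # orientation atan2(row diff, col diff) as printed
    max_refine_moves: int = 5

    def __post_init__(self) -> None:
        if self.base_sigma <= 0:
            raise ValueError("base_sigma must be > 0")
        if self.scales_per_octave < 2:
            raise ValueError("scales_per_octave must be >= 2")
        if self.contrast_threshold < 0:
            raise ValueError("contrast_threshold must be >= 0")
        if self.edge_ratio_threshold <= 0:
            raise ValueError("edge_ratio_threshold must be > 0")

    @property
    def k(self) -> float:
        """Scale factor between adjacent layers, 2^(1/s) > 1."""
        return 2.0 ** (1.0 / self.scales_per_octave)

    @property
    def layers_per_octave(self) -> int:
        return self.scales_per_octave + 3


@dataclass
class ScaleSpace:
    """Per-octave Gaussian stacks plus (after build_dog) the DoG stacks.

    gaussians[o][i] has absolute scale base_sigma * k^i * 2^o; octave o is
    sampled at stride 2^o of the base grid.
    """

    config: ScaleSpaceConfig
    gaussians: list[list[np.ndarray]]
    sigmas: list[list[float]]  # absolute sigma per (octave, layer)
    dog: list[np.ndarray] = field(default_factory=list)  # (layers-1, h, w) per octave

    @property
    def n_octaves(self) -> int:
        return len(self.gaussians)

    def octave_sigma(self, octave: int, layer: float) -> float:
        """Scale relative to the octave's own sampling grid."""
        return self.config.base_sigma * self.config.k ** layer


def gaussian_kernel_2d(sigma: float, radius: int | None = None) -> np.ndarray:
    """Discrete bivariate Gaussian G(x, y, sigma), renormalised to sum 1.

    Truncated at ``radius`` (default ceil(4 sigma)) samples from the centre.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if radius is None:
        radius = math.ceil(4 * sigma)
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    kernel = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)
    return kernel / kernel.sum()


def discrete_gaussian_kernel_1d(sigma: float) -> np.ndarray:
    """Lindeberg's discrete Gaussian T(n; sigma^2) = e^(-t) I_n(t), t = sigma^2.

    Unlike a sampled continuous Gaussian, this kernel satisfies the semigroup
    property exactly under discrete convolution, so incremental scale-space
    construction is indistinguishable from direct smoothing at the target
    scale.  Truncated where the tail is negligible and renormalised to sum 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    t = sigma * sigma
    radius = int(np.ceil(4.0 * sigma + 3.0))
    n = np.arange(-radius, radius + 1)
    kernel = special.ive(np.abs(n), t)
    return kernel / kernel.sum()


def smooth(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Separable discrete-Gaussian smoothing with mirror (reflect) borders.

    Half-sample reflection is preserved by symmetric convolution, so repeated
    smoothing composes exactly by scale quadrature even at the borders.
    """
    kernel = discrete_gaussian_kernel_1d(sigma)
    out = ndimage.correlate1d(np.asarray(frame, dtype=float), kernel, axis=0,
                              mode="reflect")
    return ndimage.correlate1d(out, kernel, axis=1, mode="reflect")


def _auto_octaves(shape: tuple[int, int]) -> int:
    return max(1, int(math.floor(math.log2(min(shape) / _MIN_OCTAVE_SIZE))) + 1)


def build_scale_space(frame: np.ndarray, cfg: ScaleSpaceConfig | None = None) -> ScaleSpace:
    """Construct the Gaussian pyramid of ``frame``.

    Layers are built incrementally: layer i is layer i-1 smoothed by the
    quadrature increment, which by the Gaussian semigroup property equals a
    single smoothing at sigma_i.
    """
    cfg = cfg or ScaleSpaceConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    n_oct = _auto_octaves(frame.shape)
    if cfg.octave_count is not None:
        if cfg.octave_count > n_oct:
            logger.warning(
                "image %s supports only %d octaves (%d requested)",
                frame.shape, n_oct, cfg.octave_count,
            )
        else:
            n_oct = cfg.octave_count
    s = cfg.scales_per_octave
    k = cfg.k

    # octave-relative sigma ladder and incremental blurs
    ladder = [cfg.base_sigma * k**i for i in range(cfg.layers_per_octave)]
    increments = [
        math.sqrt(ladder[i] ** 2 - ladder[i - 1] ** 2)
        for i in range(1, cfg.layers_per_octave)
    ]

    first_blur = math.sqrt(max(cfg.base_sigma**2 - cfg.assumed_blur**2, 1e-10))
    current = smooth(frame, first_blur)

    gaussians: list[list[np.ndarray]] = []
    sigmas: list[list[float]] = []
    for o in range(n_oct):
        layers = [current]
        for inc in increments:
            layers.append(smooth(layers[-1], inc))
        gaussians.append(layers)
        sigmas.append([sig * 2.0**o for sig in ladder])
        # seed next octave from the layer at 2*base_sigma (index s)
        current = layers[s][::2, ::2]
    return ScaleSpace(config=cfg, gaussians=gaussians, sigmas=sigmas)


def build_dog(space: ScaleSpace) -> ScaleSpace:
    """Fill the difference-of-Gaussians stacks: D_i = L_{i+1} - L_i, exactly."""
    space.dog = [
        np.stack([layers[i + 1] - layers[i] for i in range(len(layers) - 1)])
        for layers in space.gaussians
    ]
    return space
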