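"""Weighted iterative Lucas-Kanade flow with a coarse-to-fine pyramid.

The estimator assumes brightness constancy inside a small window around the
tracked point: if the template frame is F and the moving frame is G, the
displacement b satisfies G(x + b) ~ F(x) for every sample x of the window.
Each iteration linearises G about the current estimate and solves the
weighted least-squares normal equations

    (sum w g g^T) db = sum w (F(x) - G(x + b)) g,      g = grad G(x + b),

where the per-pixel weights w(x) = 1 / max(|G(x + b) - F(x)|, eps) emphasise
pixels that already agree — a residual-reciprocal weighting that de-weights
decorrelated speckle.  Subpixel sampling is bilinear; gradients are central
differences sampled at the warped position.

Large motions exceed the linearisation radius of a single window, so the
estimate is run coarse-to-fine over an image pyramid whose levels are built
with the 3 x 3 binomial stencil (1/4 centre, 1/8 edge neighbours, 1/16
diagonal neighbours) and 2x decimation; each finer level starts from twice
the coarser result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["LKConfig", "FlowEstimate", "lk_refine", "build_lk_pyramid", "pyramid_flow"]

logger = logging.getLogger(__name__)

# level l = correlate(level l-1, stencil)[::2, ::2]
PYRAMID_STENCIL = np.array([
    [1.0, 2.0, 1.0],
    [2.0, 4.0, 2.0],
    [1.0, 2.0, 1.0],
]) / 16.0


@dataclass(frozen=True)
class LKConfig:
    """window is the patch half-width S: the window spans (2S+1) x (2S+1)."""

    window: int = 7
    max_iterations: int = 20
    convergence_tol: float = 0.01
    weight_epsilon: float = 1e-3
    pyramid_levels: int = 3

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window half-width must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")


@dataclass
class FlowEstimate:
    b: np.ndarray            # (d_row, d_col) in pixels, F -> G
    iterations_used: int
    converged: bool
    residual: float          # weighted mean |G(x+b) - F(x)|


def _sample(img: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [rows, cols], order=1, mode="nearest")


def lk_refine(
    frame_f: np.ndarray,
    frame_g: np.ndarray,
    point,
    b0=(0.0, 0.0),
    cfg: LKConfig | None = None,
) -> FlowEstimate:
    """Iteratively refine the displacement of ``point`` from F to G.

    Raises ValueError when the window around the point (plus the initial
    displacement) does not fit inside the frames.
    """
    cfg = cfg or LKConfig()
    frame_f = np.asarray(frame_f, dtype=float)
    frame_g = np.asarray(frame_g, dtype=float)
    r, c = float(point[0]), float(point[1])
    b = np.asarray(b0, dtype=float).copy()
    s = cfg.window
    h, w = frame_f.shape

    if not (s <= r <= h - 1 - s and s <= c <= w - 1 - s):
        raise ValueError("patch around point leaves frame F: out of bounds")
    if not (s <= r + b[0] <= frame_g.shape[0] - 1 - s
            and s <= c + b[1] <= frame_g.shape[1] - 1 - s):
        raise ValueError("displaced patch leaves frame G: out of bounds")

    ax = np.arange(-s, s + 1, dtype=float)
    prr, pcc = np.meshgrid(r + ax, c + ax, indexing="ij")
    template = _sample(frame_f, prr, pcc)
    g_row_img, g_col_img = np.gradient(frame_g)

    eps = cfg.weight_epsilon
    iterations = 0
    converged = False
    residual = np.inf
    for iterations in range(1, cfg.max_iterations + 1):
        rr, cc = prr + b[0], pcc + b[1]
        warped = _sample(frame_g, rr, cc)
        g_r = _sample(g_row_img, rr, cc)
        g_c = _sample(g_col_img, rr, cc)
        diff = warped - template
        wgt = 1.0 / np.maximum(np.abs(diff), eps)
        residual = float(np.sum(wgt * np.abs(diff)) / np.sum(wgt))

        a11 = np.sum(wgt * g_r * g_r)
        a12 = np.sum(wgt * g_r * g_c)
        a22 = np.sum(wgt * g_c * g_c)
        if a11 + a22 < 1e-12:
            logger.debug("zero gradient over the whole patch; flagging")
            return FlowEstimate(b=b, iterations_used=iterations,
                                converged=False, residual=residual)
        rhs = -np.array([np.sum(wgt * diff * g_r), np.sum(wgt * diff * g_c)])
        a = np.array([[a11, a12], [a12, a22]])
        step, *_ = np.linalg.lstsq(a, rhs, rcond=1e-10)
        b = b + step
        if float(np.hypot(*step)) < cfg.convergence_tol:
            converged = True
            break
        # keep the window inside G; drifting out ends the iteration flagged
        if not (s <= r + b[0] <= frame_g.shape[0] - 1 - s
                and s <= c + b[1] <= frame_g.shape[1] - 1 - s):
            logger.debug("window drifted out of frame G during iteration")
            return FlowEstimate(b=b, iterations_used=iterations,
                                converged=False, residual=residual)
    return FlowEstimate(b=b, iterations_used=iterations,
                        converged=converged, residual=residual)


def build_lk_pyramid(frame: np.ndarray, levels: int) -> list[np.ndarray]:
    """Multi-resolution stack; level 0 is the input, each level the binomial
    smoothing of the previous decimated by 2 (sizes round up)."""
    frame = np.asarray(frame, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if min(frame.shape) < 2 ** levels:
        raise ValueError("too many pyramid levels for this image size")
    pyramid = [frame]
    for _ in range(levels - 1):
        smoothed = ndimage.correlate(pyramid[-1], PYRAMID_STENCIL, mode="nearest")
        pyramid.append(smoothed[::2, ::2])
    return pyramid


def pyramid_flow(
    frame_f: np.ndarray,
    frame_g: np.ndarray,
    point,
    cfg: LKConfig | None = None,
    b0=(0.0, 0.0),
) -> FlowEstimate:
    """Coarse-to-fine displacement of ``point`` from F to G.

    The coarsest level starts from ``b0`` scaled down to that level; each
    finer level starts from twice the coarser estimate.  A level that fails
    (window out of bounds) falls back to the doubled coarser estimate and the
    final result is flagged unconverged.
    """
    cfg = cfg or LKConfig()
    levels = cfg.pyramid_levels
    pyr_f = build_lk_pyramid(frame_f, levels)
    pyr_g = build_lk_pyramid(frame_g, levels)
    point = np.asarray(point, dtype=float)

    b = np.asarray(b0, dtype=float) / 2.0 ** (levels - 1)
    total_iterations = 0
    converged = True
    residual = np.inf
    for level in range(levels - 1, -1, -1):
        pt = point / 2.0**level
        try:
            est = lk_refine(pyr_f[level], pyr_g[level], pt, b, cfg)
            b = est.b
            total_iterations += est.iterations_used
            converged = converged and est.converged
            residual = est.residual
        except ValueError:
            logger.debug("level %d failed; falling back to doubled estimate", level)
            converged = False
        if level > 0:
            b = b * 2.0
    return FlowEstimate(b=b, iterations_used=total_iterations,
                        converged=converged, residual=residual)
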