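"""Tolerance-gated speckle tracking over a frame sequence.

For every consecutive frame pair the pipeline denoises both frames, extracts
and describes keypoints, matches them with the ratio test, assigns each
tracked point the accepted match nearest its current position, optionally
polishes the implied displacement with coarse-to-fine Lucas-Kanade, and
applies the tolerance gate: a per-frame displacement larger than ``tolerance``
pixels marks the point lost for that frame, recorded with the (0, 0)
sentinel.  Lost points keep their last known position internally and, with
``reacquire`` (default), may resume tracking when a plausible match
reappears near it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptor import DescriptorConfig, compute_descriptors
from .detect import detect_keypoints
from .flow import LKConfig, pyramid_flow
from .matching import MatchConfig, match_images
from .preprocess import MeanFilterSpec, mean_filter
from .scalespace import ScaleSpaceConfig, build_dog, build_scale_space

__all__ = [
    "TrackConfig",
    "Trajectory",
    "tolerance_gate",
    "track_sequence",
    "export_trajectories",
    "read_trajectories",
    "contraction_curve",
]

logger = logging.getLogger(__name__)

LOST_SENTINEL = (0.0, 0.0)


@dataclass(frozen=True)
class TrackConfig:
    """Pipeline parameters; sub-configs cover each stage."""

    tolerance: float = 10.0
    refine_with_lk: bool = True
    reacquire: bool = True
    denoise: bool = True
    filter_spec: MeanFilterSpec = field(default_factory=MeanFilterSpec)
    scale_cfg: ScaleSpaceConfig = field(default_factory=ScaleSpaceConfig)
    desc_cfg: DescriptorConfig = field(default_factory=DescriptorConfig)
    match_cfg: MatchConfig = field(default_factory=MatchConfig)
    lk_cfg: LKConfig = field(default_factory=LKConfig)

    def __post_init__(self) -> None:
        if not 1.0 <= self.tolerance <= 20.0:
            raise ValueError("tolerance must lie in [1, 20] pixels")


@dataclass
class Trajectory:
    """Per-frame (row, col) record of one tracked point with lost flags.

    Lost frames store the (0, 0) sentinel and set the flag.
    """

    point_id: int
    rows: np.ndarray
    cols: np.ndarray
    lost: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.rows)

    def position(self, t: int) -> np.ndarray:
        return np.array([self.rows[t], self.cols[t]])


def tolerance_gate(prev, candidate, tolerance: float) -> bool:
    """Accept iff the Euclidean displacement is <= tolerance (inclusive)."""
    prev = np.asarray(prev, dtype=float)
    candidate = np.asarray(candidate, dtype=float)
    return float(np.hypot(*(candidate - prev))) <= tolerance


def _frame_features(frame: np.ndarray, cfg: TrackConfig):
    """Denoise, detect and describe one frame; returns (denoised, kps, descs)."""
    den = mean_filter(frame, cfg.filter_spec) if cfg.denoise else np.asarray(
        frame, dtype=float)
    space = build_dog(build_scale_space(den, cfg.scale_cfg))
    kps = detect_keypoints(den, cfg.scale_cfg, space=space)
    descs, kept = compute_descriptors(space, kps, cfg.desc_cfg)
    return den, kept, descs


def track_sequence(
    frames,
    seeds,
    cfg: TrackConfig | None = None,
) -> list[Trajectory]:
    """Track ``seeds`` (list of (row, col)) through an ordered frame sequence."""
    cfg = cfg or TrackConfig()
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    seeds = np.asarray(seeds, dtype=float)
    h, w = frames[0].shape
    if np.any(seeds < 0) or np.any(seeds[:, 0] > h - 1) or np.any(seeds[:, 1] > w - 1):
        raise ValueError("seed points must lie inside frame 0")

    n_frames, n_pts = len(frames), len(seeds)
    rows = np.zeros((n_pts, n_frames))
    cols = np.zeros((n_pts, n_frames))
    lost = np.zeros((n_pts, n_frames), dtype=bool)
    rows[:, 0], cols[:, 0] = seeds[:, 0], seeds[:, 1]
    current = seeds.copy()            # last known position per point
    active = np.ones(n_pts, dtype=bool)

    den_prev, kps_prev, desc_prev = _frame_features(frames[0], cfg)
    for t in range(1, n_frames):
        den_cur, kps_cur, desc_cur = _frame_features(frames[t], cfg)
        if len(kps_prev) == 0 or len(desc_cur) < 2:
            matches = []
        else:
            matches = match_images(desc_prev, desc_cur, cfg.match_cfg)
        logger.info(
            "frame %d: %d features, %d matches", t, len(kps_cur), len(matches)
        )
        if matches:
            pos_a = np.array([kps_prev[m.index_a].position for m in matches])
            pos_b = np.array([kps_cur[m.index_b].position for m in matches])
            ratios = np.array([m.r for m in matches])
        for i in range(n_pts):
            if not active[i] and not cfg.reacquire:
                lost[i, t] = True
                continue
            ok = False
            if matches:
                dists = np.hypot(*(pos_a - current[i]).T)
                order = np.lexsort((ratios, dists))
                j = order[0]
                delta = pos_b[j] - pos_a[j]
                candidate = current[i] + delta
                if cfg.refine_with_lk:
                    try:
                        est = pyramid_flow(den_prev, den_cur, current[i],
                                           cfg.lk_cfg, b0=delta)
                        if est.converged:
                            candidate = current[i] + est.b
                    except ValueError:
                        pass
                inside = (0 <= candidate[0] <= h - 1) and (0 <= candidate[1] <= w - 1)
                ok = inside and tolerance_gate(current[i], candidate, cfg.tolerance)
            if ok:
                current[i] = candidate
                rows[i, t], cols[i, t] = candidate
                active[i] = True
            else:
                rows[i, t], cols[i, t] = LOST_SENTINEL
                lost[i, t] = True
                active[i] = False
        den_prev, kps_prev, desc_prev = den_cur, kps_cur, desc_cur
        n_lost = int(lost[:, t].sum())
        logger.info("frame %d: %d tracked, %d lost", t, n_pts - n_lost, n_lost)
    return [
        Trajectory(point_id=i, rows=rows[i], cols=cols[i], lost=lost[i])
        for i in range(n_pts)
    ]


def export_trajectories(trajectories: list[Trajectory], path) -> None:
    """Write a per-point per-frame CSV table.

    Columns: point_id, frame, abscissa (col), ordinate (row), lost; lost
    frames emit the 0, 0 sentinel.
    """
    if not trajectories:
        raise ValueError("no trajectories to export")
    records = []
    for traj in trajectories:
        for t in range(traj.n_frames):
            records.append({
                "point_id": traj.point_id,
                "frame": t,
                "abscissa": traj.cols[t],
                "ordinate": traj.rows[t],
                "lost": bool(traj.lost[t]),
            })
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    """Read back a trajectory table written by :func:`export_trajectories`."""
    df = pd.read_csv(path)
    out = []
    for pid, group in df.groupby("point_id", sort=True):
        group = group.sort_values("frame")
        out.append(Trajectory(
            point_id=int(pid),
            rows=group["ordinate"].to_numpy(dtype=float),
            cols=group["abscissa"].to_numpy(dtype=float),
            lost=group["lost"].to_numpy(dtype=bool),
        ))
    return out


def contraction_curve(
    trajectories: list[Trajectory], reference=None
) -> np.ndarray:
    """Per-frame mean distance of surviving points from a reference,
    normalised to frame 0.

    ``reference`` is a fixed (row, col) point; None uses the per-frame
    centroid of surviving points.  Frames where every point is lost give NaN.
    A zero frame-0 value leaves the series unnormalised.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    n_frames = trajectories[0].n_frames
    series = np.full(n_frames, np.nan)
    for t in range(n_frames):
        pts = np.array([
            [tr.rows[t], tr.cols[t]] for tr in trajectories if not tr.lost[t]
        ])
        if len(pts) == 0:
            continue
        ref = np.asarray(reference, float) if reference is not None \
            else pts.mean(axis=0)
        series[t] = float(np.mean(np.hypot(*(pts - ref).T)))
    if np.isfinite(series[0]) and series[0] > 0:
        series = series / series[0]
    return series
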