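"""Reading and writing frames, keypoint tables and match tables.

Frames travel as 16-bit PNG / TIFF on disk and float [0, 1] arrays in memory;
tabular artefacts (keypoints, descriptors, matches, ground truth) are plain
CSV handled by pandas.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detect import Keypoint
from .matching import MatchPair
from .preprocess import to_grayscale

__all__ = [
    "load_frame",
    "load_frames",
    "save_frame",
    "keypoints_to_frame",
    "keypoints_from_frame",
    "save_descriptors",
    "load_descriptors",
    "matches_to_frame",
]

_U16 = 65535


def load_frame(path) -> np.ndarray:
    """One grayscale frame as float in [0, 1]."""
    img = np.asarray(iio.imread(path))
    img = to_grayscale(img)
    info = np.iinfo(img.dtype) if np.issubdtype(img.dtype, np.integer) else None
    img = img.astype(float)
    if info is not None:
        img = img / info.max
    elif img.max() > 1.0:
        img = img / img.max()
    return img


def load_frames(source) -> list[np.ndarray]:
    """A frame sequence from a directory of images or a multi-page TIFF."""
    source = Path(source)
    if source.is_dir():
        paths = sorted(
            p for p in source.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not paths:
            raise ValueError(f"no PNG/TIFF frames found in {source}")
        return [load_frame(p) for p in paths]
    stack = np.asarray(iio.imread(source))
    if stack.ndim == 2:
        stack = stack[None]
    frames = []
    for page in stack:
        scale = np.iinfo(stack.dtype).max if np.issubdtype(stack.dtype, np.integer) else 1.0
        frames.append(to_grayscale(page).astype(float) / scale)
    return frames


def save_frame(path, frame: np.ndarray) -> None:
    """Write a float [0, 1] frame as 16-bit grayscale."""
    data = np.clip(np.asarray(frame, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (data * _U16 + 0.5).astype(np.uint16))


def keypoints_to_frame(keypoints: list[Keypoint]) -> pd.DataFrame:
    return pd.DataFrame({
        "id": np.arange(len(keypoints)),
        "row": [k.row for k in keypoints],
        "col": [k.col for k in keypoints],
        "sigma": [k.sigma for k in keypoints],
        "response": [k.response for k in keypoints],
        "orientation_rad": [k.orientation for k in keypoints],
    })


def keypoints_from_frame(df: pd.DataFrame) -> list[Keypoint]:
    return [
        Keypoint(row=r.row, col=r.col, octave=0, layer=0, sigma=r.sigma,
                 response=r.response, orientation=r.orientation_rad)
        for r in df.itertuples()
    ]


def save_descriptors(path, descriptors: np.ndarray, ids=None) -> None:
    ids = np.arange(len(descriptors)) if ids is None else np.asarray(ids)
    df = pd.DataFrame(descriptors,
                      columns=[f"v{i}" for i in range(descriptors.shape[1])])
    df.insert(0, "id", ids)
    df.to_csv(path, index=False)


def load_descriptors(path):
    df = pd.read_csv(path)
    ids = df["id"].to_numpy()
    return ids, df.drop(columns="id").to_numpy(dtype=float)


def matches_to_frame(matches: list[MatchPair]) -> pd.DataFrame:
    return pd.DataFrame({
        "index_a": [m.index_a for m in matches],
        "index_b": [m.index_b for m in matches],
        "d_min": [m.d_min for m in matches],
        "d_min2": [m.d_min2 for m in matches],
        "r": [m.r for m in matches],
    })
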