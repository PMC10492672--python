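"""Mask-to-kinematics feature extraction.

Each segmentation mask is reduced to 21 scalars: for every one of the seven
instrument-part classes, the mask centroid (x, y) normalized to [0, 1] by
image width/height and the pixel area normalized by total pixel count.
Absent classes contribute a (0, 0, 0) triplet, keeping the dimensionality
fixed for the scoring network. Frame features are stacked over time into a
variable-length T x 21 sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_PART_CLASSES = 7
N_FEATURES = 3 * N_PART_CLASSES  # x1..x7, y1..y7, a1..a7

FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{p}{c}" for p in ("x", "y", "a") for c in range(1, N_PART_CLASSES + 1))


def extract_frame_features(mask: np.ndarray) -> np.ndarray:
    """21-vector [x1..x7, y1..y7, a1..a7] from one labeled mask.

    x = mean column index / (width-1), y = mean row index / (height-1),
    a = pixel count / (height*width); classes with no pixels are zeroed.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.isin(np.unique(mask), np.arange(8)).all():
        raise ValueError("mask labels must lie in 0..7")
    h, w = mask.shape
    out = np.zeros(N_FEATURES)
    for c in range(1, N_PART_CLASSES + 1):
        rows, cols = np.nonzero(mask == c)
        if rows.size == 0:
            continue
        out[c - 1] = cols.mean() / max(w - 1, 1)
        out[N_PART_CLASSES + c - 1] = rows.mean() / max(h - 1, 1)
        out[2 * N_PART_CLASSES + c - 1] = rows.size / (h * w)
    return out


@dataclass
class FeatureSequence:
    """Rectangular T x 21 feature matrix with its frame-stride metadata."""

    data: np.ndarray
    stride: int = 1

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != N_FEATURES:
            raise ValueError(f"sequence must be T x {N_FEATURES}")
        if self.data.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        if not np.isfinite(self.data).all():
            raise ValueError("sequence contains non-finite values")

    def __len__(self) -> int:
        return self.data.shape[0]

    # -- persistence (CSV with the fixed 21-column header, or NPZ) --------
    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.data, columns=list(FEATURE_COLUMNS)).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, stride: int = 1) -> "FeatureSequence":
        df = pd.read_csv(path)
        if list(df.columns) != list(FEATURE_COLUMNS):
            raise ValueError("unexpected feature CSV header")
        return cls(df.to_numpy(), stride=stride)

    def to_npz(self, path: str | Path) -> None:
        np.savez(path, data=self.data, stride=np.array(self.stride))

    @classmethod
    def from_npz(cls, path: str | Path) -> "FeatureSequence":
        with np.load(path) as f:
            return cls(f["data"], stride=int(f["stride"]))


def assemble_sequence(frames, stride: int = 1) -> FeatureSequence:
    """Build a FeatureSequence from masks or precomputed 21-vectors,
    keeping every ``stride``-th frame (length = ceil(n/stride))."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    rows = []
    for item in frames[::stride]:
        item = np.asarray(item)
        if item.ndim == 2:
            rows.append(extract_frame_features(item))
        elif item.shape == (N_FEATURES,):
            rows.append(item.astype(float))
        else:
            raise ValueError("each frame must be a mask or a 21-vector")
    seq = FeatureSequence(np.stack(rows), stride=stride)
    assert len(seq) == math.ceil(len(frames) / stride)
    return seq
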