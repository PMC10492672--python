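"""PNG and JSON I/O helpers: RGB frames, indexed label masks, rating records."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .records import RatingRecord

# fixed palette for the 8 mask labels (background + 7 instrument parts)
_PALETTE = [
    (0, 0, 0), (230, 60, 60), (240, 160, 40), (230, 230, 60),
    (70, 200, 70), (60, 160, 230), (120, 70, 220), (230, 90, 200),
]


def save_frame_png(frame: np.ndarray, path: str | Path) -> None:
    """Write an H x W x 3 float [0,1] frame as 8-bit RGB PNG."""
    arr = np.clip(np.asarray(frame) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def load_frame_png(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=float)
    return arr / 255.0


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write an H x W label mask (values 0..7) as single-channel indexed PNG."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > 7:
        raise ValueError("mask labels must lie in 0..7")
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = [v for rgb in _PALETTE for v in rgb]
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(path)


def load_mask_png(path: str | Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode not in ("P", "L"):
        raise ValueError(f"expected indexed mask PNG, got mode {img.mode}")
    return np.asarray(img, dtype=np.uint8)


def save_rating_json(record: RatingRecord, path: str | Path) -> None:
    Path(path).write_text(record.to_json() + "\n")


def load_rating_json(path: str | Path) -> RatingRecord:
    return RatingRecord.from_json(Path(path).read_text())


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
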