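"""Instrument-part semantic segmentation.

An encoder-decoder (U-net style) network with five encoding blocks, three
bottleneck blocks and five decoding blocks maps an H x W x 3 frame to an
H x W x 8 per-class score map (background + 7 instrument parts). Two
attention mechanisms augment the plain U-net:

* a global attention layer at the bottleneck — single-head spatial
  self-attention over the coarsest feature map, letting every position
  attend to the whole image;
* cross image attention in selected decoder blocks — decoder features act
  as queries against the skip-connection features (keys/values), weighting
  which encoder detail is merged back in.

Training uses per-pixel cross-entropy with random scale/rotate/shift
augmentation applied identically to frame and mask; evaluation data are
never augmented. Quality is measured as mean intersection-over-union (IoU),
excluding classes absent from both masks.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import AffineTransform, warp

from . import nn
from .nn import Tensor

__all__ = [
    "SegModelConfig", "AugmentParams", "SegTrainParams", "Segmenter",
    "build_segmenter", "augment_pair", "iou", "predict_mask",
    "train_segmenter", "save_checkpoint", "load_checkpoint",
]

N_CLASSES = 8  # background + 7 instrument parts


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture hyperparameters; block counts default to five encoders,
    five decoders and three bottleneck blocks."""

    encoder_blocks: int = 5
    decoder_blocks: int = 5
    bottleneck_blocks: int = 3
    base_channels: int = 8
    global_attention: bool = True
    cross_attention_decoders: tuple[int, ...] = (0, 1)
    seed: int = 0

    def __post_init__(self):
        if self.encoder_blocks != self.decoder_blocks:
            raise ValueError("encoder and decoder block counts must match")
        if min(self.encoder_blocks, self.bottleneck_blocks,
               self.base_channels) < 1:
            raise ValueError("block counts and channels must be >= 1")
        if any(d < 0 or d >= self.decoder_blocks
               for d in self.cross_attention_decoders):
            raise ValueError("cross_attention_decoders out of range")


class _SpatialSelfAttention(nn.Module):
    """Single-head attention over the positions of a (B,C,H,W) map.

    Without a context this is spatial self-attention; with one, queries come
    from ``x`` and keys/values from the context map (cross image attention).
    """

    def __init__(self, channels: int, rng, context_channels: int | None = None):
        cc = context_channels or channels
        self.q = nn.Conv2d(channels, channels, 1, rng)
        self.k = nn.Conv2d(cc, channels, 1, rng)
        self.v = nn.Conv2d(cc, channels, 1, rng)
        self.scale = 1.0 / np.sqrt(channels)

    def __call__(self, x: Tensor, context: Tensor | None = None) -> Tensor:
        ctx = x if context is None else context
        B, C, H, W = x.shape
        Hc, Wc = ctx.shape[2], ctx.shape[3]
        q = self.q(x).reshape(B, C, H * W).transpose(0, 2, 1)
        k = self.k(ctx).reshape(B, C, Hc * Wc)
        v = self.v(ctx).reshape(B, C, Hc * Wc).transpose(0, 2, 1)
        attn = ((q @ k) * self.scale).softmax(axis=-1)   # (B, HW, HcWc)
        out = (attn @ v).transpose(0, 2, 1).reshape(B, C, H, W)
        return x + out  # residual


class Segmenter(nn.Module):
    """Attention-augmented U-net over fixed channel schedule
    base * 2^min(depth, 2)."""

    def __init__(self, config: SegModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        nb = config.encoder_blocks
        ch = [config.base_channels * 2 ** min(i, 2) for i in range(nb)]

        self.enc_convs, self.enc_downs = [], []
        c_in = 3
        for c in ch:
            self.enc_convs.append(nn.Conv2d(c_in, c, 3, rng, padding=1))
            self.enc_downs.append(nn.Conv2d(c, c, 3, rng, stride=2,
                                            padding=1))
            c_in = c
        self.bottleneck = [nn.Conv2d(c_in, c_in, 3, rng, padding=1)
                           for _ in range(config.bottleneck_blocks)]
        self.global_attn = (_SpatialSelfAttention(c_in, rng)
                            if config.global_attention else None)
        self.dec_convs, self.cross_attns = [], {}
        self._cross_attn_modules = []  # so Module.parameters() sees them
        for d in range(nb):
            skip_c = ch[nb - 1 - d]
            self.dec_convs.append(
                nn.Conv2d(c_in + skip_c, skip_c, 3, rng, padding=1))
            if d in config.cross_attention_decoders:
                attn = _SpatialSelfAttention(c_in, rng,
                                             context_channels=skip_c)
                self.cross_attns[d] = attn
                self._cross_attn_modules.append(attn)
            c_in = skip_c
        self.head = nn.Conv2d(c_in, N_CLASSES, 1, rng)

    def _check_dims(self, h: int, w: int) -> None:
        f = 2 ** self.config.encoder_blocks
        if h % f or w % f:
            raise ValueError(
                f"input {h}x{w} not divisible by {f} "
                f"({self.config.encoder_blocks} downsamplings); "
                f"pad the frame to a multiple of {f}")

    def forward_graph(self, frames: np.ndarray) -> Tensor:
        """(B,H,W,3) float frames -> (B,8,H,W) class-score Tensor."""
        B, H, W, _ = frames.shape
        self._check_dims(H, W)
        x = Tensor(np.transpose(frames, (0, 3, 1, 2)))
        skips = []
        for conv, down in zip(self.enc_convs, self.enc_downs):
            x = conv(x).relu()
            skips.append(x)
            x = down(x).relu()
        for conv in self.bottleneck:
            x = conv(x).relu()
        if self.global_attn is not None:
            x = self.global_attn(x)
        for d, conv in enumerate(self.dec_convs):
            skip = skips[len(skips) - 1 - d]
            x = x.upsample2x()
            if d in self.cross_attns:
                x = self.cross_attns[d](x, context=skip)
            x = conv(nn.concatenate([x, skip], axis=1)).relu()
        return self.head(x)


def build_segmenter(config: SegModelConfig | None = None) -> Segmenter:
    """Construct a segmenter; identical config+seed gives identical
    initial parameters."""
    return Segmenter(config or SegModelConfig())


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentParams:
    """Ranges for the random projection transform applied during training."""

    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_deg: tuple[float, float] = (-15.0, 15.0)
    shift_frac: tuple[float, float] = (-0.1, 0.1)


def augment_pair(frame: np.ndarray, mask: np.ndarray,
                 params: AugmentParams | None = None,
                 seed: int | np.random.Generator = 0):
    """Apply one random scale/rotate/shift transform identically to frame
    (bilinear) and mask (nearest-neighbour, labels preserved).

    Degenerate draws (|scale| < 1e-3) are rejected and resampled.
    """
    params = params or AugmentParams()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if frame.shape[:2] != mask.shape:
        raise ValueError("frame and mask dimensions must match")
    h, w = mask.shape
    for _ in range(100):
        scale = rng.uniform(*params.scale_range)
        if abs(scale) >= 1e-3:
            break
    else:
        raise ValueError("could not draw a non-degenerate scale")
    angle = np.deg2rad(rng.uniform(*params.rotation_deg))
    tr = rng.uniform(params.shift_frac[0], params.shift_frac[1]) * h
    tc = rng.uniform(params.shift_frac[0], params.shift_frac[1]) * w

    # rotate+scale about the image centre, then shift (x=col, y=row)
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    fwd = (AffineTransform(translation=-centre)
           + AffineTransform(scale=scale, rotation=angle)
           + AffineTransform(translation=centre + [tc, tr]))
    inv = fwd.inverse
    out_frame = warp(frame, inv, order=1, mode="constant", cval=0.0,
                     preserve_range=True)
    out_mask = warp(mask.astype(float), inv, order=0, mode="constant",
                    cval=0.0, preserve_range=True).astype(mask.dtype)
    return out_frame, out_mask


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def iou(predicted: np.ndarray, truth: np.ndarray,
        classes=range(N_CLASSES)) -> tuple[dict[int, float], float]:
    """Per-class and mean intersection-over-union.

    Classes absent from both masks are excluded from the per-class dict and
    the mean (an absent class carries no evidence either way). Returns
    ``({class: iou}, mean_iou)``; the mean of an all-empty comparison is 1.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("mask dimensions must match")
    per_class: dict[int, float] = {}
    for c in classes:
        p = predicted == c
        t = truth == c
        union = (p | t).sum()
        if union == 0:
            continue
        per_class[c] = float((p & t).sum() / union)
    mean = float(np.mean(list(per_class.values()))) if per_class else 1.0
    return per_class, mean


def predict_mask(segmenter: Segmenter, frame: np.ndarray) -> np.ndarray:
    """Per-pixel argmax label map; ties resolve to the lower class index."""
    scores = segmenter.forward_graph(frame[None]).data[0]
    return scores.argmax(axis=0).astype(np.uint8)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegTrainParams:
    steps: int = 300
    batch_size: int = 4
    lr: float = 3e-3
    augment: AugmentParams | None = AugmentParams()
    eval_every: int = 25
    seed: int = 0


def _pixel_cross_entropy(logits: Tensor, masks: np.ndarray) -> Tensor:
    B, C, H, W = logits.shape
    flat = logits.transpose(0, 2, 3, 1).reshape(B * H * W, C)
    logp = flat.log_softmax(axis=-1)
    picked = logp[np.arange(B * H * W), masks.reshape(-1)]
    return -picked.mean()


def _mean_iou_over(segmenter, pairs) -> float:
    vals = [iou(predict_mask(segmenter, f), m)[1] for f, m in pairs]
    return float(np.mean(vals))


def train_segmenter(train_pairs, config: SegModelConfig | None = None,
                    params: SegTrainParams | None = None,
                    eval_pairs=None):
    """Train on (frame, mask) pairs; returns (segmenter, curve) where
    ``curve`` rows are (batch_index, split, iou) for train and eval.

    The returned segmenter carries the parameters of the best checkpoint
    (highest eval IoU seen, falling back to the final state when no eval
    pairs are given). Evaluation pairs are never augmented.
    """
    train_pairs = list(train_pairs)
    if not train_pairs:
        raise ValueError("empty training dataset")
    if all((m == 0).all() for _, m in train_pairs):
        warnings.warn("dataset contains no positive (instrument) pixels")
    params = params or SegTrainParams()
    segmenter = build_segmenter(config)
    opt = nn.Adam(segmenter.parameters(), lr=params.lr)
    rng = np.random.default_rng(params.seed)

    curve: list[tuple[int, str, float]] = []
    best_iou, best_state = -1.0, None
    for step in range(params.steps):
        idx = rng.integers(len(train_pairs), size=params.batch_size)
        batch = []
        for i in idx:
            f, m = train_pairs[i]
            if params.augment is not None:
                f, m = augment_pair(f, m, params.augment, rng)
            batch.append((f, m))
        frames = np.stack([f for f, _ in batch])
        masks = np.stack([m for _, m in batch]).astype(int)
        logits = segmenter.forward_graph(frames)
        loss = _pixel_cross_entropy(logits, masks)
        opt.zero_grad()
        loss.backward()
        opt.step()

        pred = logits.data.argmax(axis=1)
        batch_iou = float(np.mean([iou(p, m)[1]
                                   for p, m in zip(pred, masks)]))
        curve.append((step, "train", batch_iou))
        last = step == params.steps - 1
        if eval_pairs and (step % params.eval_every == 0 or last):
            ev = _mean_iou_over(segmenter, eval_pairs)
            curve.append((step, "eval", ev))
            if ev > best_iou:  # checkpoint on eval improvement
                best_iou = ev
                best_state = [a.copy() for a in segmenter.state_arrays()]
    if best_state is not None:
        segmenter.load_state_arrays(best_state)
    return segmenter, curve


# ---------------------------------------------------------------------------
# checkpointing (binary npz with embedded config JSON)
# ---------------------------------------------------------------------------

def save_checkpoint(segmenter: Segmenter, path: str | Path) -> None:
    cfg = json.dumps(dataclasses.asdict(segmenter.config))
    arrays = {f"p{i}": a for i, a in enumerate(segmenter.state_arrays())}
    np.savez(path, config=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> Segmenter:
    with np.load(path) as f:
        cfg = json.loads(bytes(f["config"]).decode())
        cfg["cross_attention_decoders"] = tuple(
            cfg["cross_attention_decoders"])
        segmenter = build_segmenter(SegModelConfig(**cfg))
        arrays = [f[f"p{i}"] for i in range(len(f.files) - 1)]
    segmenter.load_state_arrays(arrays)
    return segmenter
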