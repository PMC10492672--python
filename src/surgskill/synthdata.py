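"""Synthetic fixtures: instrument scenes with ground-truth masks, and
trajectory feature sequences with ratings from a known deterministic rule.

Real surgical video and its ratings are not publicly distributable, so the
package ships generators that emulate the two inputs every downstream stage
needs:

* ``generate_scene`` draws up to seven elongated capsule-shaped
  "instrument parts" with distinct hues on a smoothly textured background
  and returns the image together with its exact per-pixel label mask.
  Left-arm parts (classes 1-3) are placed toward the left of the frame,
  right-arm parts (4-6) toward the right, the needle (7) anywhere.
* ``generate_trajectory_case`` simulates smooth random-walk instrument
  kinematics as a T x 21 feature sequence and labels it by applying a fixed
  :class:`ScoreRule` to summary statistics of the noise-free latent
  trajectory — giving ground truth that a trained scoring network can be
  tested against (parameter recovery).

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import colorsys
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .features import FeatureSequence, N_PART_CLASSES
from .io import (save_frame_png, save_json, save_mask_png, save_rating_json)
from .records import (ALL_SUBCATEGORIES, GEARS_SUBCATEGORIES,
                      OSATS_SUBCATEGORIES, TASKS, RatingRecord)

__all__ = [
    "SceneSpec", "TrajectorySpec", "ScoreRule", "generate_scene",
    "generate_trajectory_case", "generate_dataset", "default_score_rule",
    "compute_trajectory_stats", "PART_COLORS",
]

LEFT_CLASSES = (1, 2, 3)    # left-arm upper flexion / abduction / grasper
RIGHT_CLASSES = (4, 5, 6)   # right-arm counterparts
NEEDLE_CLASS = 7

# distinct hue per part class; shared value/specular noise added per scene
PART_COLORS = np.array(
    [colorsys.hsv_to_rgb(c / N_PART_CLASSES, 0.75, 0.9)
     for c in range(N_PART_CLASSES)])

# which part classes are active in each surgical task regime
TASK_ACTIVE_CLASSES = {
    "cut": (1, 2, 3, 4, 5, 6),
    "recon": (1, 2, 3, 4, 5, 6, 7),
    "bolster": (3, 6, 7),
}
# relative tempo of instrument motion per task regime
TASK_SPEED_FACTOR = {"cut": 0.6, "recon": 1.0, "bolster": 1.7}

# Mean step length below which a frame counts as idle. Set well above the
# sub-pixel observation-noise floor so pauses remain identifiable from the
# emitted (noisy) features, and well below typical active step lengths.
IDLE_SPEED_THRESHOLD = 4e-3


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``shape_params`` gives (radius_min, radius_max, length_min, length_max)
    in pixels for the capsule drawn per part; ``background_texture`` is
    (noise amplitude, Gaussian smoothing scale in pixels).
    """

    image_height: int = 64
    image_width: int = 64
    parts_present: frozenset = frozenset(range(1, N_PART_CLASSES + 1))
    shape_params: tuple[float, float, float, float] = (2.0, 4.0, 10.0, 22.0)
    background_texture: tuple[float, float] = (0.12, 3.0)
    seed: int = 0

    def __post_init__(self):
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("image dimensions must be >= 32")
        parts = frozenset(int(p) for p in self.parts_present)
        if not parts <= set(range(1, N_PART_CLASSES + 1)):
            raise ValueError("parts_present must be a subset of {1..7}")
        object.__setattr__(self, "parts_present", parts)


def _capsule_pixels(h: int, w: int, p0, p1, radius: float) -> np.ndarray:
    """Boolean mask of pixels within ``radius`` of segment p0-p1."""
    rows, cols = np.mgrid[0:h, 0:w]
    d = p1 - p0
    denom = float(d @ d)
    if denom < 1e-12:
        t = np.zeros((h, w))
    else:
        t = ((rows - p0[0]) * d[0] + (cols - p0[1]) * d[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    cr = p0[0] + t * d[0]
    cc = p0[1] + t * d[1]
    return (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one scene: returns (H x W x 3 float image in [0,1],
    H x W uint8 mask with labels in {0..7}).

    Part regions are mutually disjoint (placement is rejection-sampled);
    an empty ``parts_present`` yields a pure-background negative example.
    Raises ``ValueError`` naming the class if a part cannot be placed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    amp, smooth = spec.background_texture
    background = 0.45 + amp * gaussian_filter(rng.normal(size=(h, w)), smooth)
    image = np.repeat(background[:, :, None], 3, axis=2)
    image += rng.normal(0.0, 0.01, size=image.shape)
    mask = np.zeros((h, w), dtype=np.uint8)

    r_lo, r_hi, len_lo, len_hi = spec.shape_params
    for cls in sorted(spec.parts_present):
        if cls in LEFT_CLASSES:
            col_range = (0.0, 0.55 * w)
        elif cls in RIGHT_CLASSES:
            col_range = (0.45 * w, w - 1.0)
        else:
            col_range = (0.0, w - 1.0)
        placed = False
        for _ in range(300):
            radius = rng.uniform(r_lo, r_hi)
            length = rng.uniform(len_lo, len_hi)
            r0 = rng.uniform(radius, h - 1 - radius)
            c0 = rng.uniform(col_range[0] + radius,
                             max(col_range[0] + radius + 1,
                                 col_range[1] - radius))
            theta = rng.uniform(0, 2 * np.pi)
            p0 = np.array([r0, c0])
            p1 = p0 + length * np.array([np.sin(theta), np.cos(theta)])
            p1[0] = np.clip(p1[0], 0, h - 1)
            p1[1] = np.clip(p1[1], col_range[0], col_range[1])
            pix = _capsule_pixels(h, w, p0, p1, radius)
            if pix.sum() >= 1 and not (pix & (mask > 0)).any():
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place part class {cls} in a "
                f"{h}x{w} image; increase image size")
        mask[pix] = cls
        shading = 1.0 + 0.15 * gaussian_filter(
            rng.normal(size=(h, w)), 1.5)[pix]  # shared specular noise
        image[pix] = PART_COLORS[cls - 1][None, :] * shading[:, None]

    return np.clip(image, 0.0, 1.0), mask


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Parameters of one simulated kinematic sequence.

    ``smoothness`` is the random-walk step scale (normalized image units per
    frame); ``idle_fraction`` the expected share of frames with near-zero
    motion; ``area_drift`` the relative per-frame area variation scale;
    ``noise_sd`` additive observation noise on the emitted features.
    """

    length_range: tuple[int, int] = (60, 120)
    smoothness: float = 0.02
    idle_fraction: float = 0.2
    area_drift: float = 0.1
    noise_sd: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.length_range[0] < 10 or self.length_range[1] < self.length_range[0]:
            raise ValueError("length_range min must be >= 10 and <= max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.idle_fraction <= 1):
            raise ValueError("idle_fraction must be in [0, 1]")

    def with_seed(self, seed: int) -> "TrajectorySpec":
        return dataclasses.replace(self, seed=int(seed))


def _simulate_latent(spec: TrajectorySpec,
                     rng: np.random.Generator,
                     task: str | None = None):
    """Noise-free latent trajectory: returns (T x 21 latent features, task)."""
    if task is None:
        task = TASKS[rng.integers(len(TASKS))]
    active = TASK_ACTIVE_CLASSES[task]
    T = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))

    # per-case kinematic regime: tempo jitter, hand asymmetry, pause rate
    speed = spec.smoothness * TASK_SPEED_FACTOR[task] * rng.lognormal(0, 0.4)
    f_left, f_right = rng.uniform(0.4, 1.6, size=2)  # one tempo per hand
    side_factor = {NEEDLE_CLASS: 1.0}
    for c in LEFT_CLASSES:
        side_factor[c] = f_left
    for c in RIGHT_CLASSES:
        side_factor[c] = f_right
    idle_p = rng.uniform(0.0, min(1.0, 2.0 * spec.idle_fraction))
    idle = rng.random(T - 1) < idle_p  # shared pauses across instruments
    drift_scale = spec.area_drift * rng.uniform(0.3, 1.7)

    latent = np.zeros((T, 3 * N_PART_CLASSES))
    for cls in active:
        i = cls - 1
        pos = np.empty((T, 2))
        pos[0] = rng.uniform(0.25, 0.75, size=2)
        steps = rng.normal(0.0, speed * side_factor[cls], size=(T - 1, 2))
        steps[idle] = 0.0
        pos[1:] = pos[0] + np.cumsum(steps, axis=0)
        pos = np.clip(pos, 0.0, 1.0)
        base_area = rng.uniform(0.01, 0.06)
        da = rng.normal(0.0, drift_scale * base_area, size=T - 1)
        area = np.clip(base_area + np.concatenate([[0.0], np.cumsum(da)]),
                       0.003, 0.2)
        latent[:, i] = pos[:, 1]                       # x
        latent[:, N_PART_CLASSES + i] = pos[:, 0]      # y
        latent[:, 2 * N_PART_CLASSES + i] = area
    return latent, task


def compute_trajectory_stats(latent: np.ndarray) -> dict[str, float]:
    """Summary statistics of a noise-free latent trajectory.

    mean_speed  — mean per-frame centroid step length over active parts;
    jerk        — mean absolute change of that step length (motion roughness);
    idle_frac   — fraction of transitions with mean step below threshold;
    asymmetry   — absolute left/right-hand mean-speed difference
                  (normalized units per frame);
    area_var    — mean absolute per-frame change of total instrument area
                  (x100), a dispersion measure of area over time.
    """
    x = latent[:, :N_PART_CLASSES]
    y = latent[:, N_PART_CLASSES:2 * N_PART_CLASSES]
    a = latent[:, 2 * N_PART_CLASSES:]
    active = np.nonzero(a.max(axis=0) > 0)[0]
    if active.size == 0:
        return {"mean_speed": 0.0, "jerk": 0.0, "idle_frac": 1.0,
                "asymmetry": 0.0, "area_var": 0.0}
    dx = np.diff(x[:, active], axis=0)
    dy = np.diff(y[:, active], axis=0)
    step = np.hypot(dx, dy)               # (T-1, n_active)
    frame_speed = step.mean(axis=1)
    mean_speed = float(frame_speed.mean())
    jerk = float(np.abs(np.diff(frame_speed)).mean()) if len(frame_speed) > 1 else 0.0
    idle_frac = float((frame_speed < IDLE_SPEED_THRESHOLD).mean())

    def _side_speed(classes):
        cols = [np.where(active == c - 1)[0] for c in classes]
        cols = [c[0] for c in cols if c.size]
        return float(step[:, cols].mean()) if cols else None

    v_left = _side_speed(LEFT_CLASSES)
    v_right = _side_speed(RIGHT_CLASSES)
    if v_left is None or v_right is None:
        asymmetry = 0.0
    else:
        asymmetry = abs(v_left - v_right)
    total_area = a[:, active].sum(axis=1)
    area_var = float(np.abs(np.diff(total_area)).mean() * 100.0)
    return {"mean_speed": mean_speed, "jerk": jerk, "idle_frac": idle_frac,
            "asymmetry": asymmetry, "area_var": area_var}


STAT_NAMES = ("mean_speed", "jerk", "idle_frac", "asymmetry", "area_var")


@dataclass(frozen=True)
class ScoreRule:
    """Deterministic mapping from trajectory statistics to ratings.

    Each of the 13 GEARS/OSATS subcategories is assigned one statistic and a
    direction; the score is the 1-5 bin of that statistic against four fixed
    cut-points (reversed when direction = -1). The task label equals the
    simulated regime. The default cut-points are quintiles of each statistic
    under the default :class:`TrajectorySpec`, giving balanced labels.
    """

    thresholds: dict[str, tuple[float, float, float, float]]
    assignment: dict[str, tuple[str, int]]

    def __post_init__(self):
        if set(self.assignment) != set(ALL_SUBCATEGORIES):
            raise ValueError("assignment must cover all 13 subcategories")
        for stat, sign in self.assignment.values():
            if stat not in self.thresholds or sign not in (-1, 1):
                raise ValueError("bad assignment entry")

    def score_subcategory(self, key: str, stats: dict[str, float]) -> int:
        stat, sign = self.assignment[key]
        level = 1 + int(np.sum(stats[stat] > np.asarray(self.thresholds[stat])))
        return level if sign > 0 else 6 - level

    def apply(self, stats: dict[str, float]) -> tuple[dict, dict]:
        gears = {k: self.score_subcategory(k, stats)
                 for k in GEARS_SUBCATEGORIES}
        osats = {k: self.score_subcategory(k, stats)
                 for k in OSATS_SUBCATEGORIES}
        return gears, osats


def default_score_rule(spec: TrajectorySpec | None = None,
                       n_calibration: int = 400,
                       seed: int = 20230627) -> ScoreRule:
    """Rule with quintile cut-points calibrated on the default spec."""
    spec = spec or TrajectorySpec()
    rng = np.random.default_rng(seed)
    samples = {s: [] for s in STAT_NAMES}
    for _ in range(n_calibration):
        latent, _ = _simulate_latent(spec, rng)
        stats = compute_trajectory_stats(latent)
        for s in STAT_NAMES:
            samples[s].append(stats[s])
    thresholds = {
        s: tuple(np.quantile(samples[s], [0.2, 0.4, 0.6, 0.8]))
        for s in STAT_NAMES
    }
    assignment = {
        key: (STAT_NAMES[i % len(STAT_NAMES)], 1 if i % 2 == 0 else -1)
        for i, key in enumerate(ALL_SUBCATEGORIES)
    }
    return ScoreRule(thresholds=thresholds, assignment=assignment)


def generate_trajectory_case(
        spec: TrajectorySpec, rule: ScoreRule,
        surgery_id: str = "synthetic",
        task: str | None = None) -> tuple[FeatureSequence, RatingRecord]:
    """One labeled case: observed noisy sequence + rating record whose
    scores are the rule applied to the noise-free latent trajectory."""
    rng = np.random.default_rng(spec.seed)
    latent, task = _simulate_latent(spec, rng, task)
    stats = compute_trajectory_stats(latent)
    gears, osats = rule.apply(stats)
    observed = latent.copy()
    if spec.noise_sd > 0:
        observed += rng.normal(0.0, spec.noise_sd, size=latent.shape)
    active_cols = latent.max(axis=0) > 0
    observed[:, ~active_cols] = 0.0  # absent instruments stay exactly zero
    observed = np.clip(observed, 0.0, 1.0)
    record = RatingRecord(surgery_id=surgery_id, gears=gears, osats=osats,
                          task=task)
    return FeatureSequence(observed), record


# ---------------------------------------------------------------------------
# dataset on disk
# ---------------------------------------------------------------------------

def generate_dataset(n_surgeries: int, out_dir: str | Path,
                     scene_spec: SceneSpec | None = None,
                     traj_spec: TrajectorySpec | None = None,
                     rule: ScoreRule | None = None,
                     seed: int = 0, frames_per_surgery: int = 3) -> Path:
    """Write a full synthetic corpus: one directory per surgery containing
    PNG frames + masks, a feature-sequence CSV and a rating JSON, plus a
    manifest listing the surgery ids (the bootstrap resampling unit)."""
    if n_surgeries < 1:
        raise ValueError("n_surgeries must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene_spec = scene_spec or SceneSpec()
    traj_spec = traj_spec or TrajectorySpec()
    rule = rule or default_score_rule(traj_spec)

    ids = []
    for i in range(n_surgeries):
        sid = f"surgery_{i:04d}"
        ids.append(sid)
        sdir = out / sid
        (sdir / "frames").mkdir(parents=True, exist_ok=True)
        (sdir / "masks").mkdir(parents=True, exist_ok=True)
        base = seed * 1_000_003 + i * 101
        for j in range(frames_per_surgery):
            sspec = dataclasses.replace(scene_spec, seed=(base + j) % 2**31)
            frame, mask = generate_scene(sspec)
            save_frame_png(frame, sdir / "frames" / f"frame_{j:03d}.png")
            save_mask_png(mask, sdir / "masks" / f"mask_{j:03d}.png")
        tspec = traj_spec.with_seed((base + 7919) % 2**31)
        seq, record = generate_trajectory_case(tspec, rule, surgery_id=sid)
        seq.to_csv(sdir / "features.csv")
        save_rating_json(record, sdir / "rating.json")
    save_json(ids, out / "manifest.json")
    return out
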