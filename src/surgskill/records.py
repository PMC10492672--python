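"""Rating records and model-output containers for GEARS/OSATS scoring.

GEARS (Global Evaluative Assessment of Robotic Skills) has six subcategories
and OSATS (Objective Structured Assessment of Technical Skills) has seven;
each is scored on an ordinal 1-5 scale by a human rater. A record also
carries the surgical task label and a validity flag (records marked invalid,
e.g. because a video segment mixed two surgeons, are excluded from training
and metrics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

GEARS_SUBCATEGORIES: tuple[str, ...] = (
    "depth_perception", "bimanual_dexterity", "efficiency",
    "force_sensitivity", "autonomy", "robotic_control",
)
OSATS_SUBCATEGORIES: tuple[str, ...] = (
    "respect_for_tissue", "time_and_motion", "instrument_handling",
    "knowledge_of_instruments", "assistance", "flow_of_operation",
    "knowledge_of_procedure",
)
ALL_SUBCATEGORIES: tuple[str, ...] = GEARS_SUBCATEGORIES + OSATS_SUBCATEGORIES
TASKS: tuple[str, ...] = ("cut", "recon", "bolster")
N_LEVELS = 5  # ordinal rating levels 1..5


def _check_scores(scores: dict[str, int], keys: tuple[str, ...],
                  scale: str) -> None:
    if set(scores) != set(keys):
        raise ValueError(f"{scale} scores must have keys {keys}")
    for k, v in scores.items():
        if not (1 <= int(v) <= N_LEVELS):
            raise ValueError(f"{scale} score {k}={v} outside 1..{N_LEVELS}")


@dataclass
class RatingRecord:
    """One rater's assessment of one surgery."""

    surgery_id: str
    gears: dict[str, int]
    osats: dict[str, int]
    task: str
    rater_id: str = "rater0"
    surgeon_role: str = "attending"
    valid: bool = True

    def __post_init__(self):
        _check_scores(self.gears, GEARS_SUBCATEGORIES, "GEARS")
        _check_scores(self.osats, OSATS_SUBCATEGORIES, "OSATS")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.surgeon_role not in ("trainee", "attending"):
            raise ValueError("surgeon_role must be 'trainee' or 'attending'")

    def subcategory_scores(self) -> dict[str, int]:
        return {**self.gears, **self.osats}

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RatingRecord":
        return cls(**json.loads(text))


@dataclass
class ModelOutputs:
    """Per-head probability distributions produced by the scoring network.

    ``gears``: (6, 5) — one distribution over levels 1..5 per subcategory;
    ``osats``: (7, 5); ``task``: (3,) over (cut, recon, bolster).
    """

    gears: np.ndarray
    osats: np.ndarray
    task: np.ndarray
    attention_weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.gears = np.asarray(self.gears, dtype=float)
        self.osats = np.asarray(self.osats, dtype=float)
        self.task = np.asarray(self.task, dtype=float)
        if self.gears.shape != (len(GEARS_SUBCATEGORIES), N_LEVELS):
            raise ValueError("gears head must be shape (6, 5)")
        if self.osats.shape != (len(OSATS_SUBCATEGORIES), N_LEVELS):
            raise ValueError("osats head must be shape (7, 5)")
        if self.task.shape != (len(TASKS),):
            raise ValueError("task head must be shape (3,)")
        for name, arr in (("gears", self.gears), ("osats", self.osats),
                          ("task", self.task[None, :])):
            if (arr < 0).any():
                raise ValueError(f"{name} probabilities must be >= 0")
            if not np.allclose(arr.sum(axis=-1), 1.0, atol=1e-5):
                raise ValueError(f"{name} distributions must sum to 1")
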