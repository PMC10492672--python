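"""Surgery-level evaluation: splits, bootstrap with out-of-bag scoring,
the 0.632 estimator, and per-subcategory reporting.

The unit of resampling is the *surgery*: all records and sequences from one
surgery travel together, so no surgery ever appears in both a training set
and its matched evaluation set. Each bootstrap round draws surgeries with
replacement to form the training multiset; surgeries never drawn form the
round's out-of-bag (OOB) evaluation set. The headline estimate combines
training and OOB performance with the classical 0.632 rule,

    est = 0.368 * train + 0.632 * oob,

appropriate when the two are similarly distributed (0.632 = 1 - 1/e is the
large-n probability that an item appears in a bootstrap resample).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .features import FeatureSequence
from .records import ALL_SUBCATEGORIES, RatingRecord
from .scoring import (ScoreModelConfig, ScoreTrainParams, evaluate_scorer,
                      train_scorer)

__all__ = [
    "split_by_surgery", "run_bootstrap", "estimate_632",
    "subcategory_report", "bootstrap_distinct_fraction", "BootstrapResult",
]

Case = tuple[FeatureSequence, RatingRecord]


def _surgery_ids(cases: list[Case]) -> list[str]:
    seen: dict[str, None] = {}
    for _, rec in cases:
        seen.setdefault(rec.surgery_id)
    return list(seen)


def split_by_surgery(cases: list[Case], train_fraction: float = 0.8,
                     seed: int = 0) -> tuple[list[Case], list[Case]]:
    """Split cases at surgery granularity; e.g. 50 surgeries at 0.8 give
    40 training and 10 evaluation surgeries."""
    ids = _surgery_ids(cases)
    if len(ids) < 2:
        raise ValueError("need at least 2 surgeries to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    if n_train < 1 or n_train >= len(ids):
        raise ValueError("train_fraction leaves an empty split")
    train_ids = {ids[i] for i in order[:n_train]}
    train = [c for c in cases if c[1].surgery_id in train_ids]
    ev = [c for c in cases if c[1].surgery_id not in train_ids]
    return train, ev


def estimate_632(train_metric: float, oob_metric: float) -> float:
    """0.632-rule combination of training and out-of-bag performance."""
    for v in (train_metric, oob_metric):
        if not (0.0 <= v <= 1.0):
            raise ValueError("metrics must lie in [0, 1]")
    return 0.368 * train_metric + 0.632 * oob_metric


@dataclass
class BootstrapResult:
    """Per-round train/OOB metrics plus the combined 0.632 estimates."""

    rounds: list[dict]

    def __post_init__(self):
        if not self.rounds:
            raise ValueError("bootstrap produced no rounds")

    def _mean(self, split: str, key: str) -> float:
        return float(np.mean([r[split][key] for r in self.rounds]))

    def combined(self) -> dict[str, float]:
        return {
            key: estimate_632(self._mean("train", key),
                              self._mean("oob", key))
            for key in ("gears_acc", "osats_acc", "task_acc")
        }


def run_bootstrap(cases: list[Case], rounds: int = 50,
                  model_config: ScoreModelConfig | None = None,
                  train_params: ScoreTrainParams | None = None,
                  seed: int = 0) -> BootstrapResult:
    """Repeatedly retrain on surgery-level bootstrap resamples.

    Each round draws n surgeries with replacement (duplicates train the
    model on repeated cases, as bootstrap prescribes); the out-of-bag
    surgeries form the evaluation set. Rounds whose OOB set would be empty
    are redrawn. Per-round records hold overall and per-subcategory
    metrics for both splits.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    cases = [c for c in cases if c[1].valid]
    ids = _surgery_ids(cases)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 surgeries to bootstrap")
    by_id: dict[str, list[Case]] = {sid: [] for sid in ids}
    for c in cases:
        by_id[c[1].surgery_id].append(c)
    rng = np.random.default_rng(seed)

    out_rounds = []
    for r in range(rounds):
        for _ in range(1000):
            draw = rng.integers(n, size=n)
            oob_ids = [sid for i, sid in enumerate(ids)
                       if i not in set(draw)]
            if oob_ids:
                break
        else:
            raise ValueError("could not draw a round with out-of-bag data")
        train_cases = [c for i in draw for c in by_id[ids[i]]]
        oob_cases = [c for sid in oob_ids for c in by_id[sid]]
        params = train_params or ScoreTrainParams()
        params = dataclasses.replace(params, seed=params.seed + r)
        scorer, _ = train_scorer(train_cases, model_config, params)
        out_rounds.append({
            "round": r,
            "oob_fraction": len(oob_ids) / n,
            "train_ids": sorted({ids[i] for i in draw}),
            "oob_ids": sorted(oob_ids),
            "train": evaluate_scorer(scorer, train_cases),
            "oob": evaluate_scorer(scorer, oob_cases),
        })
    return BootstrapResult(out_rounds)


def _quartiles(values) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"q1": float(q1), "median": float(med), "q3": float(q3)}


def subcategory_report(result: BootstrapResult) -> dict:
    """Fig-4-style report: per-subcategory accuracy quartiles for train and
    OOB splits, residual quartiles with 1.5-IQR outliers, and overall
    "mean ± sd" summaries."""
    report: dict = {"subcategories": {}, "overall": {}}
    for key in ALL_SUBCATEGORIES:
        entry: dict = {}
        for split in ("train", "oob"):
            accs = [r[split]["per_subcategory"][key]["acc"]
                    for r in result.rounds]
            entry[f"{split}_accuracy"] = _quartiles(accs)
        res = [x for r in result.rounds
               for x in r["oob"]["per_subcategory"][key]["residuals"]]
        q = _quartiles(res)
        iqr = q["q3"] - q["q1"]
        lo, hi = q["q1"] - 1.5 * iqr, q["q3"] + 1.5 * iqr
        entry["residuals"] = q | {
            "outliers": sorted({float(x) for x in res if x < lo or x > hi})}
        report["subcategories"][key] = entry
    for metric in ("gears_acc", "osats_acc", "task_acc"):
        vals = [r["oob"][metric] for r in result.rounds]
        report["overall"][metric] = (
            f"{np.mean(vals):.2f} ± {np.std(vals):.2f}")
    report["combined_632"] = result.combined()
    return report


def bootstrap_distinct_fraction(n: int, replicates: int,
                                seed: int = 0) -> float:
    """Mean fraction of distinct items in a size-n resample drawn with
    replacement from n items; converges to 1 - 1/e ~ 0.632 as n grows."""
    rng = np.random.default_rng(seed)
    fracs = [np.unique(rng.integers(n, size=n)).size / n
             for _ in range(replicates)]
    return float(np.mean(fracs))
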