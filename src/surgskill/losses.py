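"""Training losses and agreement metrics for ordinal multi-task scoring.

The central object is the adapted weighted-kappa training loss

    l_WK = log(1 - kappa + eps),   kappa = 1 - sum(w*O) / sum(w*E),

where ``O`` is the observed rating-confusion matrix between two raters (or
between model and rater), ``E`` the chance-expected matrix (outer product of
the marginal score counts, rescaled to the total of ``O``) and
``w[i,j] = |i-j|^k / (N-1)^k`` the ordinal penalty matrix. ``kappa = 1`` is
perfect agreement, ``kappa = 0`` agreement at chance level. Counting
matrices are non-differentiable, so training uses a soft observed matrix
built from predicted class probabilities; hard counts are used for all
reported metrics.

Also provided: cross-entropy multi-task loss, exact-match accuracy and
signed residuals, the evaluation metrics used for GEARS/OSATS agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .records import (ALL_SUBCATEGORIES, GEARS_SUBCATEGORIES, N_LEVELS,
                      OSATS_SUBCATEGORIES, TASKS, RatingRecord)

__all__ = [
    "KappaConfig", "weight_matrix", "observed_matrix", "soft_observed",
    "expected_matrix", "weighted_kappa_loss", "cohen_kappa",
    "multitask_loss", "matching_accuracy", "residuals",
]


@dataclass(frozen=True)
class KappaConfig:
    """Weighted-kappa hyperparameters: N rating levels, penalty exponent k,
    and the epsilon guarding log(0) at perfect agreement."""

    n_levels: int = N_LEVELS
    k: float = 1.0
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("need at least 2 rating levels")
        if self.k < 1:
            raise ValueError("penalty exponent k must be >= 1")
        if not (0 < self.epsilon < 1):
            raise ValueError("epsilon must be in (0, 1)")


def weight_matrix(n_levels: int = N_LEVELS, k: float = 1.0) -> np.ndarray:
    """Ordinal penalty matrix w[i,j] = |i-j|^k / (N-1)^k.

    Zero on the diagonal, 1 at maximal disagreement. The absolute value
    makes w a genuine penalty for every k (k=1 gives the standard
    linear-weighted kappa).
    """
    if n_levels < 2:
        raise ValueError("need at least 2 rating levels")
    idx = np.arange(n_levels, dtype=float)
    return np.abs(idx[:, None] - idx[None, :]) ** k / (n_levels - 1) ** k


def observed_matrix(scores_a, scores_b,
                    n_levels: int = N_LEVELS) -> np.ndarray:
    """Hard rating-confusion counts: O[i,j] = #items scored i+1 by rater A
    and j+1 by rater B (scores given on the 1..N scale)."""
    a = np.asarray(scores_a, dtype=int)
    b = np.asarray(scores_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be equal-length 1-D")
    if ((a < 1) | (a > n_levels) | (b < 1) | (b > n_levels)).any():
        raise ValueError(f"scores must lie in 1..{n_levels}")
    O = np.zeros((n_levels, n_levels))
    np.add.at(O, (a - 1, b - 1), 1.0)
    return O


def soft_observed(probabilities: Tensor | np.ndarray, true_scores,
                  n_levels: int = N_LEVELS) -> Tensor:
    """Differentiable observed matrix: row = true score (one-hot), columns
    carry the predicted probability mass. With one-hot probabilities this
    reduces exactly to :func:`observed_matrix`. Total mass equals n."""
    probs = nn.as_tensor(probabilities)
    t = np.asarray(true_scores, dtype=int)
    if probs.shape != (t.size, n_levels):
        raise ValueError("probabilities must be (n_samples, n_levels)")
    if ((t < 1) | (t > n_levels)).any():
        raise ValueError(f"scores must lie in 1..{n_levels}")
    onehot = np.zeros((t.size, n_levels))
    onehot[np.arange(t.size), t - 1] = 1.0
    # O = onehot^T @ probs, rows indexed by truth
    return Tensor(onehot.T) @ probs


def expected_matrix(O: Tensor | np.ndarray):
    """Chance-expected matrix: outer product of the row and column marginals
    of ``O``, rescaled so that sum(E) = sum(O)."""
    is_tensor = isinstance(O, Tensor)
    Od = O.data if is_tensor else np.asarray(O, dtype=float)
    if Od.sum() <= 0:
        raise ValueError("observed matrix has zero total mass")
    Ot = nn.as_tensor(O)
    row = Ot.sum(axis=1, keepdims=True)
    col = Ot.sum(axis=0, keepdims=True)
    E = (row @ col) / Ot.sum()
    return E if is_tensor else E.data


def weighted_kappa_loss(O: Tensor | np.ndarray, E: Tensor | np.ndarray,
                        w: np.ndarray, epsilon: float = 1e-6):
    """Weighted kappa and its log-decoupled loss log(1 - kappa + eps).

    Returns ``(kappa, loss)``; gradients flow through a Tensor-valued ``O``
    (the soft observed matrix), enabling use as a training objective.
    """
    is_tensor = isinstance(O, Tensor) or isinstance(E, Tensor)
    Ot, Et, wt = nn.as_tensor(O), nn.as_tensor(E), nn.as_tensor(w)
    denom = float((Et.data * w).sum())
    if denom <= 0:
        raise ValueError(
            "sum(w*E) = 0: degenerate marginals, kappa undefined")
    kappa = 1.0 - ((wt * Ot).sum() / (wt * Et).sum())
    loss = (1.0 - kappa + epsilon).log()
    if is_tensor:
        return kappa, loss
    return float(kappa.data), float(loss.data)


def cohen_kappa(scores_a, scores_b, n_levels: int = N_LEVELS,
                k: float = 1.0) -> float:
    """Weighted Cohen's kappa between two hard score vectors (k=1: linear)."""
    O = observed_matrix(scores_a, scores_b, n_levels)
    E = expected_matrix(O)
    w = weight_matrix(n_levels, k)
    kappa, _ = weighted_kappa_loss(O, E, w)
    return kappa


# ---------------------------------------------------------------------------
# multi-task training loss
# ---------------------------------------------------------------------------

def _cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood; logits (B, C), integer targets (B,)."""
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(len(targets)), targets]
    return -picked.mean()


def multitask_loss(head_logits: dict[str, Tensor],
                   records: list[RatingRecord],
                   loss_kind: str = "CE",
                   kappa_config: KappaConfig | None = None) -> Tensor:
    """Total training loss over the 13 subcategory heads plus the task head.

    ``head_logits`` maps "gears" -> (B, 6, 5), "osats" -> (B, 7, 5) and
    "task" -> (B, 3) logit tensors. ``loss_kind`` selects cross-entropy
    ("CE") or the weighted-kappa loss ("WK") for the ordinal subcategory
    heads; the 3-way task head (unordered classes) always trains with CE.
    With WK the observed matrix is accumulated over the mini-batch per head,
    since kappa is undefined for a single sample; a head whose batch has a
    vanishing chance-disagreement term falls back to CE for that batch.
    """
    if loss_kind not in ("CE", "WK"):
        raise ValueError("loss_kind must be 'CE' or 'WK'")
    records = [r for r in records if r.valid]
    if not records:
        raise ValueError("no valid records in batch")
    cfg = kappa_config or KappaConfig()
    w = weight_matrix(cfg.n_levels, cfg.k)

    total: Tensor | None = None
    for scale, keys in (("gears", GEARS_SUBCATEGORIES),
                        ("osats", OSATS_SUBCATEGORIES)):
        logits = head_logits[scale]  # (B, n_heads, 5)
        for h, key in enumerate(keys):
            truth = np.array([getattr(r, scale)[key] for r in records])
            head = logits[:, h, :]
            if loss_kind == "CE":
                term = _cross_entropy(head, truth - 1)
            else:
                probs = head.softmax(axis=-1)
                O = soft_observed(probs, truth, cfg.n_levels)
                E = expected_matrix(O)
                if float((E.data * w).sum()) <= 1e-12:
                    term = _cross_entropy(head, truth - 1)
                else:
                    _, term = weighted_kappa_loss(O, E, w, cfg.epsilon)
            total = term if total is None else total + term

    task_truth = np.array([TASKS.index(r.task) for r in records])
    total = total + _cross_entropy(head_logits["task"], task_truth)
    return total


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

def matching_accuracy(pred: dict[str, int], truth: dict[str, int]) -> float:
    """Fraction of subcategories whose scores match exactly."""
    if set(pred) != set(truth):
        raise KeyError("prediction and truth must share subcategory keys")
    if not pred:
        raise ValueError("empty score set")
    return sum(pred[k] == truth[k] for k in pred) / len(pred)


def residuals(pred: dict[str, int], truth: dict[str, int]) -> dict[str, int]:
    """Signed per-subcategory differences, predicted minus true (positive
    means the model rates skill higher than the human rater)."""
    if set(pred) != set(truth):
        raise KeyError("prediction and truth must share subcategory keys")
    return {k: pred[k] - truth[k] for k in pred}


def scale_accuracies(pred: dict[str, int],
                     truth: dict[str, int]) -> tuple[float, float]:
    """Exact-match accuracy computed separately for GEARS (6 subcategories)
    and OSATS (7 subcategories)."""
    g = matching_accuracy({k: pred[k] for k in GEARS_SUBCATEGORIES},
                          {k: truth[k] for k in GEARS_SUBCATEGORIES})
    o = matching_accuracy({k: pred[k] for k in OSATS_SUBCATEGORIES},
                          {k: truth[k] for k in OSATS_SUBCATEGORIES})
    return g, o
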