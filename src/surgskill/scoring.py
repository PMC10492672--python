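"""Multi-task scoring network (mtCNN) over kinematic feature sequences.

The network reads a variable-length T x 21 sequence of instrument features
through two pathways: a temporal-convolution trunk producing per-timestep
feature vectors, and an attention pathway producing normalized per-timestep
weights. The weighted features are collapsed by averaging, which makes the
summary — and hence every output shape — independent of sequence length.
Three attention-pooling variants are provided:

* ``WG`` (weight gated): 1-D convolutions over the trunk output followed by
  a softmax across time;
* ``SA`` (self-attention): a set of weight vectors from a tanh projection,
  as in structured self-attentive sequence embeddings;
* ``DP`` (direct self-attention pooling): learned query vectors attend over
  convolutional keys/values, replacing temporal pooling entirely.

A shared trunk feeds 14 heads: six GEARS and seven OSATS subcategory
classifiers (5 ordinal levels each) and a 3-way surgical-task classifier.
All temporal convolutions use edge ("same") padding so that a constant
input yields constant features — and therefore uniform attention weights.

Sequences shorter than ``min_len`` are left-padded with zeros and the
padded positions are masked out of the attention softmax.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .features import N_FEATURES, N_PART_CLASSES, FeatureSequence
from .losses import KappaConfig, multitask_loss, scale_accuracies
from .records import (GEARS_SUBCATEGORIES, N_LEVELS, OSATS_SUBCATEGORIES,
                      TASKS, ModelOutputs, RatingRecord)

__all__ = [
    "ScoreModelConfig", "ScoreTrainParams", "Scorer", "build_scorer",
    "forward", "attention_weights", "predict_labels", "train_scorer",
    "save_checkpoint", "load_checkpoint",
]

ATTENTION_VARIANTS = ("WG", "SA", "DP")


@dataclass(frozen=True)
class ScoreModelConfig:
    attention_variant: str = "SA"
    conv_channels: tuple[int, ...] = (32, 32, 32)
    kernel: int = 5
    attn_dim: int = 16
    attn_heads: int = 4
    head_hidden: int = 64
    min_len: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.attention_variant not in ATTENTION_VARIANTS:
            raise ValueError(
                f"attention_variant must be one of {ATTENTION_VARIANTS}")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd for same-length output")


def _conv_same(x: Tensor, conv: nn.Conv1d) -> Tensor:
    """1-D convolution with edge replication padding (length-preserving)."""
    k = conv.weight.shape[-1]
    p = k // 2
    if p:
        left = [x[:, :, 0:1]] * p
        right = [x[:, :, -1:]] * p
        x = nn.concatenate(left + [x] + right, axis=2)
    return conv(x)


class _Head(nn.Module):
    """Classifier head over the pooled sequence summary.

    Two hidden layers: several rating statistics are ratios of pooled
    quantities (e.g. relative hand speeds), which need depth two to
    approximate well from uncentered nonnegative activations.
    """

    def __init__(self, n_in: int, hidden: int, n_out: int, rng):
        if hidden > 0:
            self.fc1 = nn.Linear(n_in, hidden, rng)
            self.fc2 = nn.Linear(hidden, hidden, rng)
            self.out = nn.Linear(hidden, n_out, rng)
        else:
            self.fc1 = self.fc2 = None
            self.out = nn.Linear(n_in, n_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if self.fc1 is not None:
            x = self.fc2(self.fc1(x).relu()).relu()
        return self.out(x)


class Scorer(nn.Module):
    """Shared trunk + attention pooling + 14 classification heads."""

    def __init__(self, config: ScoreModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        # raw features + |diff| channels + per-instrument step and log-step
        c_in = 2 * N_FEATURES + 2 * 7
        self.trunk = []
        for c in config.conv_channels:
            self.trunk.append(nn.Conv1d(c_in, c, config.kernel, rng))
            c_in = c
        C, R, d = c_in, config.attn_heads, config.attn_dim

        v = config.attention_variant
        if v == "WG":
            self.attn_layers = [nn.Conv1d(C, C, config.kernel, rng),
                                nn.Conv1d(C, R, 1, rng)]
            pool_dim = R * C
        elif v == "SA":
            self.attn_layers = [nn.Conv1d(C, d, 1, rng),
                                nn.Conv1d(d, R, 1, rng)]
            pool_dim = R * C
        else:  # DP
            self.attn_layers = [nn.Conv1d(C, d, 1, rng),   # keys
                                nn.Conv1d(C, d, 1, rng)]   # values
            self.queries = Tensor(rng.normal(0, 1.0 / np.sqrt(d), (R, d)),
                                  requires_grad=True)
            pool_dim = R * d
        self.attn_pool_dim = pool_dim
        pool_dim += 2 * N_FEATURES + 2 * 7  # stem skip-pathway means
        self.pool_dim = pool_dim

        # one small MLP per head (a hidden layer lets a head express
        # nonlinear combinations of pooled summaries, e.g. speed ratios);
        # the trunk and pooling stay shared across all 14 heads
        self.gears_heads = [_Head(pool_dim, config.head_hidden, N_LEVELS, rng)
                            for _ in GEARS_SUBCATEGORIES]
        self.osats_heads = [_Head(pool_dim, config.head_hidden, N_LEVELS, rng)
                            for _ in OSATS_SUBCATEGORIES]
        self.task_head = _Head(pool_dim, config.head_hidden, len(TASKS), rng)

    # -- internals ---------------------------------------------------------
    def _batch(self, seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Left-pad to a common length >= min_len; returns (B,21,T), (B,T)."""
        lengths = [s.shape[0] for s in seqs]
        if min(lengths) < 1:
            raise ValueError("sequences must have at least one frame")
        T = max(max(lengths), self.config.min_len)
        x = np.zeros((len(seqs), N_FEATURES, T))
        mask = np.zeros((len(seqs), T))
        for i, s in enumerate(seqs):
            if not np.isfinite(s).all():
                raise ValueError("sequence contains non-finite values")
            t = s.shape[0]
            x[i, :, T - t:] = s.T
            mask[i, T - t:] = 1.0
        return x, mask

    def _attention(self, h: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        """Returns (pooled (B,pool_dim), weights (B,R,T))."""
        B, C, T = h.shape
        neg = Tensor((mask[:, None, :] - 1.0) * 1e9)  # -1e9 at padding
        v = self.config.attention_variant
        if v == "WG":
            a = _conv_same(h, self.attn_layers[0]).relu()
            scores = _conv_same(a, self.attn_layers[1])
            weights = (scores + neg).softmax(axis=-1)        # (B,R,T)
            pooled = weights @ h.transpose(0, 2, 1)          # (B,R,C)
        elif v == "SA":
            u = _conv_same(h, self.attn_layers[0]).tanh()
            scores = _conv_same(u, self.attn_layers[1])
            weights = (scores + neg).softmax(axis=-1)
            pooled = weights @ h.transpose(0, 2, 1)
        else:  # DP: learned queries over conv keys/values
            k = _conv_same(h, self.attn_layers[0])           # (B,d,T)
            val = _conv_same(h, self.attn_layers[1])         # (B,d,T)
            scale = 1.0 / np.sqrt(self.config.attn_dim)
            scores = (self.queries @ k) * scale              # (B,R,T)
            weights = (scores + neg).softmax(axis=-1)
            pooled = weights @ val.transpose(0, 2, 1)        # (B,R,d)
        return pooled.reshape(B, self.attn_pool_dim), weights

    def forward_graph(self, seqs: list[np.ndarray],
                      return_attention: bool = False):
        """Head logits for a batch of (T_i, 21) sequences."""
        x, mask = self._batch(seqs)
        # kinematic stem: skill ratings describe motion, so expose per-frame
        # displacements alongside the raw positions/areas. Channels are
        # rescaled to O(1) (typical steps are ~1e-3..5e-2 in normalized
        # units) so the trunk sees well-conditioned inputs: per-feature
        # absolute differences, per-instrument planar step lengths, and a
        # log-step channel that makes scale-free contrasts (speed ratios
        # between hands) linearly accessible.
        n = N_PART_CLASSES
        d = np.abs(np.diff(x, axis=2, prepend=x[:, :, :1]))
        step = np.sqrt(d[:, :n] ** 2 + d[:, n:2 * n] ** 2)
        logstep = 0.25 * (np.log(step + 1e-4) + 5.0)
        stem = np.concatenate([x, 50.0 * d, 50.0 * step, logstep], axis=1)
        # skip pathway: masked time-average of the stem channels, handed
        # straight to the heads so plain kinematic means (per-instrument
        # speeds, areas) survive the trunk untouched
        counts = mask.sum(axis=1, keepdims=True)
        stem_mean = (stem * mask[:, None, :]).sum(axis=2) / counts
        h = Tensor(stem)
        for conv in self.trunk:
            h = _conv_same(h, conv).relu()
        pooled, weights = self._attention(h, mask)
        pooled = nn.concatenate([pooled, Tensor(stem_mean)], axis=1)
        gears = nn.stack([head(pooled) for head in self.gears_heads], axis=1)
        osats = nn.stack([head(pooled) for head in self.osats_heads], axis=1)
        logits = {"gears": gears, "osats": osats,
                  "task": self.task_head(pooled)}
        if return_attention:
            return logits, weights
        return logits


def build_scorer(config: ScoreModelConfig | None = None) -> Scorer:
    """Construct a scoring network; identical config gives identical
    initial parameters. All variants share the same trunk layout and differ
    only in the pooling block."""
    return Scorer(config or ScoreModelConfig())


def attention_weights(scorer: Scorer, sequence) -> np.ndarray:
    """Per-timestep attention weights (n_heads, T) for one sequence; for
    WG and SA each head's weights sum to 1 over valid timesteps, for DP the
    internal attention map of the pooled output is returned."""
    seq = sequence.data if isinstance(sequence, FeatureSequence) else sequence
    _, weights = scorer.forward_graph([np.asarray(seq)],
                                      return_attention=True)
    return weights.data[0]


def forward(scorer: Scorer, sequence) -> ModelOutputs:
    """Run one sequence through the scorer and return the 14 per-head
    probability distributions (plus the attention map)."""
    seq = sequence.data if isinstance(sequence, FeatureSequence) else sequence
    logits, weights = scorer.forward_graph([np.asarray(seq)],
                                           return_attention=True)
    return ModelOutputs(
        gears=_softmax_np(logits["gears"].data[0]),
        osats=_softmax_np(logits["osats"].data[0]),
        task=_softmax_np(logits["task"].data[0]),
        attention_weights=weights.data[0],
    )


def _softmax_np(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def predict_labels(outputs: ModelOutputs):
    """Hard labels from head distributions; ties resolve to the lower
    score / earlier task label (argmax convention)."""
    gears = {k: int(np.argmax(outputs.gears[i])) + 1
             for i, k in enumerate(GEARS_SUBCATEGORIES)}
    osats = {k: int(np.argmax(outputs.osats[i])) + 1
             for i, k in enumerate(OSATS_SUBCATEGORIES)}
    task = TASKS[int(np.argmax(outputs.task))]
    return gears, osats, task


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreTrainParams:
    epochs: int = 60
    batch_size: int = 32
    lr: float = 4e-3
    lr_final: float | None = None   # linear decay target; None = constant
    loss_kind: str = "CE"   # or "WK"
    kappa: KappaConfig = KappaConfig()
    seed: int = 0


def train_scorer(cases: list[tuple[FeatureSequence, RatingRecord]],
                 config: ScoreModelConfig | None = None,
                 params: ScoreTrainParams | None = None):
    """Train on (sequence, record) cases; invalid records are excluded.
    Returns (scorer, history) with per-epoch mean training loss."""
    params = params or ScoreTrainParams()
    cases = [(s, r) for s, r in cases if r.valid]
    if not cases:
        raise ValueError("no valid cases to train on")
    scorer = build_scorer(config)
    opt = nn.Adam(scorer.parameters(), lr=params.lr)
    rng = np.random.default_rng(params.seed)

    history = []
    n = len(cases)
    for epoch in range(params.epochs):
        if params.lr_final is not None and params.epochs > 1:
            frac = epoch / (params.epochs - 1)
            opt.lr = params.lr + frac * (params.lr_final - params.lr)
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, params.batch_size):
            batch = [cases[i] for i in order[lo:lo + params.batch_size]]
            seqs = [np.asarray(s.data) for s, _ in batch]
            recs = [r for _, r in batch]
            logits = scorer.forward_graph(seqs)
            loss = multitask_loss(logits, recs, params.loss_kind,
                                  params.kappa)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append((epoch, float(np.mean(losses))))
    return scorer, history


def evaluate_scorer(scorer: Scorer,
                    cases: list[tuple[FeatureSequence, RatingRecord]]):
    """Exact-match metrics over cases: returns a dict with overall GEARS /
    OSATS / task accuracy, per-subcategory accuracy and signed residuals."""
    from .losses import residuals as _residuals
    per_acc: dict[str, list[int]] = {}
    per_res: dict[str, list[int]] = {}
    g_accs, o_accs, t_hits = [], [], []
    for seq, rec in cases:
        if not rec.valid:
            continue
        gears, osats, task = predict_labels(forward(scorer, seq))
        pred = {**gears, **osats}
        truth = rec.subcategory_scores()
        g, o = scale_accuracies(pred, truth)
        g_accs.append(g)
        o_accs.append(o)
        t_hits.append(task == rec.task)
        for k, r in _residuals(pred, truth).items():
            per_acc.setdefault(k, []).append(int(pred[k] == truth[k]))
            per_res.setdefault(k, []).append(r)
    if not g_accs:
        raise ValueError("no valid cases to evaluate")
    return {
        "gears_acc": float(np.mean(g_accs)),
        "osats_acc": float(np.mean(o_accs)),
        "task_acc": float(np.mean(t_hits)),
        "per_subcategory": {
            k: {"acc": float(np.mean(per_acc[k])), "residuals": per_res[k]}
            for k in per_acc
        },
    }


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(scorer: Scorer, path) -> None:
    cfg = dataclasses.asdict(scorer.config)
    arrays = {f"p{i}": a for i, a in enumerate(scorer.state_arrays())}
    np.savez(path, config=np.frombuffer(json.dumps(cfg).encode(),
                                        dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Scorer:
    with np.load(path) as f:
        cfg = json.loads(bytes(f["config"]).decode())
        cfg["conv_channels"] = tuple(cfg["conv_channels"])
        scorer = build_scorer(ScoreModelConfig(**cfg))
        arrays = [f[f"p{i}"] for i in range(len(f.files) - 1)]
    scorer.load_state_arrays(arrays)
    return scorer
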