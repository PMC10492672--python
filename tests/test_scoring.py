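"""Scoring network: shape invariance, attention contracts, label decoding."""

import numpy as np
import pytest

from surgskill import scoring
from surgskill.records import ModelOutputs, TASKS

VARIANTS = scoring.ATTENTION_VARIANTS


@pytest.fixture(params=VARIANTS)
def scorer(request):
    return scoring.build_scorer(
        scoring.ScoreModelConfig(attention_variant=request.param, seed=1))


class TestForward:
    def test_output_shape_independent_of_length(self, scorer):
        rng = np.random.default_rng(0)
        o50 = scoring.forward(scorer, rng.random((50, 21)))
        o500 = scoring.forward(scorer, rng.random((500, 21)))
        for o in (o50, o500):
            assert o.gears.shape == (6, 5)
            assert o.osats.shape == (7, 5)
            assert o.task.shape == (3,)

    def test_distributions_normalized(self, scorer):
        o = scoring.forward(scorer,
                            np.random.default_rng(3).random((80, 21)))
        assert np.allclose(o.gears.sum(axis=-1), 1.0, atol=1e-5)
        assert np.allclose(o.osats.sum(axis=-1), 1.0, atol=1e-5)
        assert o.task.sum() == pytest.approx(1.0, abs=1e-5)

    def test_deterministic_and_seed_reproducible(self):
        x = np.random.default_rng(5).random((60, 21))
        a = scoring.build_scorer(scoring.ScoreModelConfig(seed=7))
        b = scoring.build_scorer(scoring.ScoreModelConfig(seed=7))
        assert np.allclose(scoring.forward(a, x).gears,
                           scoring.forward(b, x).gears)

    def test_feature_columns_are_positional(self, scorer):
        """Permuting the 21 feature columns changes the outputs: the
        features are instrument-specific, not exchangeable."""
        rng = np.random.default_rng(11)
        x = rng.random((70, 21))
        perm = rng.permutation(21)
        o1 = scoring.forward(scorer, x)
        o2 = scoring.forward(scorer, x[:, perm])
        assert not np.allclose(o1.gears, o2.gears)

    def test_short_sequences_left_padded(self, scorer):
        o = scoring.forward(scorer, np.random.default_rng(1).random((4, 21)))
        assert o.gears.shape == (6, 5)

    def test_non_finite_input_rejected(self, scorer):
        x = np.full((30, 21), np.nan)
        with pytest.raises(ValueError):
            scoring.forward(scorer, x)

    def test_variants_share_trunk_layout(self):
        models = [scoring.build_scorer(
            scoring.ScoreModelConfig(attention_variant=v, seed=0))
            for v in VARIANTS]
        trunk_shapes = [[tuple(c.weight.shape) for c in m.trunk]
                        for m in models]
        assert trunk_shapes[0] == trunk_shapes[1] == trunk_shapes[2]

    def test_trunk_shared_across_heads(self, scorer):
        """Structurally multi-task: all 14 heads read the same pooled
        vector produced by one trunk + pooling block."""
        n_heads = (len(scorer.gears_heads) + len(scorer.osats_heads) + 1)
        assert n_heads == 14
        in_dims = {h.fc1.weight.shape[0] for h in
                   scorer.gears_heads + scorer.osats_heads
                   + [scorer.task_head]}
        assert in_dims == {scorer.pool_dim}


class TestAttention:
    def test_weights_sum_to_one(self, scorer):
        x = np.random.default_rng(2).random((90, 21))
        w = scoring.attention_weights(scorer, x)
        assert w.shape[1] == 90
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)
        assert (w >= 0).all()

    def test_constant_input_gives_uniform_weights(self, scorer):
        T = 64
        w = scoring.attention_weights(scorer, np.full((T, 21), 0.3))
        assert np.allclose(w, 1.0 / T, atol=1e-9)


class TestPredictLabels:
    def test_one_hot_distributions_decode_exactly(self):
        g = np.zeros((6, 5))
        o = np.zeros((7, 5))
        g[np.arange(6), [0, 1, 2, 3, 4, 0]] = 1.0
        o[np.arange(7), [4, 3, 2, 1, 0, 4, 3]] = 1.0
        t = np.array([0.0, 1.0, 0.0])
        gears, osats, task = scoring.predict_labels(
            ModelOutputs(g, o, t))
        assert list(gears.values()) == [1, 2, 3, 4, 5, 1]
        assert list(osats.values()) == [5, 4, 3, 2, 1, 5, 4]
        assert task == TASKS[1]

    def test_uniform_head_ties_break_to_lowest_score(self):
        g = np.full((6, 5), 0.2)
        o = np.full((7, 5), 0.2)
        t = np.full(3, 1 / 3)
        gears, osats, task = scoring.predict_labels(ModelOutputs(g, o, t))
        assert set(gears.values()) == {1}
        assert set(osats.values()) == {1}
        assert task == TASKS[0]


def test_training_reduces_loss_on_overfit_set(trajectory_cases):
    cases = trajectory_cases[:10]
    _, history = scoring.train_scorer(
        cases, scoring.ScoreModelConfig(seed=0),
        scoring.ScoreTrainParams(epochs=15, batch_size=5, seed=0))
    assert history[-1][1] < history[0][1]


def test_checkpoint_roundtrip(tmp_path):
    model = scoring.build_scorer(scoring.ScoreModelConfig("DP", seed=3))
    x = np.random.default_rng(0).random((40, 21))
    path = tmp_path / "scorer.npz"
    scoring.save_checkpoint(model, path)
    back = scoring.load_checkpoint(path)
    assert np.allclose(scoring.forward(model, x).osats,
                       scoring.forward(back, x).osats)
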