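"""Weighted-kappa machinery, multi-task losses and agreement metrics."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from surgskill import losses, nn
from surgskill.records import (GEARS_SUBCATEGORIES, OSATS_SUBCATEGORIES,
                               RatingRecord)


class TestWeightMatrix:
    def test_linear_penalty_values(self):
        w = losses.weight_matrix(5, 1)
        assert w[0, 4] == 1.0          # maximal disagreement (scores 1 vs 5)
        assert w[1, 1] == 0.0          # diagonal
        assert w[0, 2] == 0.5          # two levels apart
        assert np.array_equal(w, w.T)
        assert (np.diag(w) == 0).all()

    def test_rejects_single_level(self):
        with pytest.raises(ValueError):
            losses.weight_matrix(1)


class TestObservedExpected:
    def test_hard_counts(self):
        O = losses.observed_matrix([1, 2], [1, 2])
        assert O[0, 0] == 1 and O[1, 1] == 1 and O.sum() == 2
        O = losses.observed_matrix([1, 1, 2], [1, 2, 2])
        assert O[0, 0] == 1 and O[0, 1] == 1 and O[1, 1] == 1

    def test_soft_equals_hard_for_one_hot(self):
        truth = np.array([1, 3, 5, 3])
        probs = np.zeros((4, 5))
        pred = [2, 3, 5, 1]
        probs[np.arange(4), np.array(pred) - 1] = 1.0
        soft = losses.soft_observed(probs, truth).data
        hard = losses.observed_matrix(truth, pred)  # rows = truth
        assert np.allclose(soft, hard)
        assert soft.sum() == pytest.approx(4)

    def test_expected_hand_example_and_conservation(self):
        O = losses.observed_matrix([1, 1, 2], [1, 2, 2])
        E = losses.expected_matrix(O)
        assert E[0, 0] == pytest.approx(2 / 3)
        assert E[0, 1] == pytest.approx(4 / 3)
        assert E[1, 0] == pytest.approx(1 / 3)
        assert E[1, 1] == pytest.approx(2 / 3)
        assert E.sum() == pytest.approx(O.sum())

    def test_expected_invariant_to_joint_permutation(self):
        rng = np.random.default_rng(3)
        O = rng.integers(0, 5, size=(5, 5)).astype(float)
        perm = rng.permutation(5)
        E = losses.expected_matrix(O)
        E_perm = losses.expected_matrix(O[np.ix_(perm, perm)])
        assert np.allclose(E[np.ix_(perm, perm)], E_perm)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            losses.observed_matrix([0, 1], [1, 1])
        with pytest.raises(ValueError):
            losses.expected_matrix(np.zeros((5, 5)))


class TestKappa:
    def test_worked_example(self):
        """a=[1,1,2], b=[1,2,2]: sum(wO)=0.25, sum(wE)=5/12, kappa=0.4."""
        O = losses.observed_matrix([1, 1, 2], [1, 2, 2])
        E = losses.expected_matrix(O)
        w = losses.weight_matrix(5, 1)
        assert (w * O).sum() == pytest.approx(0.25)
        assert (w * E).sum() == pytest.approx(5 / 12)
        kappa, _ = losses.weighted_kappa_loss(O, E, w)
        assert kappa == pytest.approx(0.4)

    def test_perfect_agreement_and_chance(self):
        a = np.tile(np.arange(1, 6), 4)
        assert losses.cohen_kappa(a, a) == pytest.approx(1.0)
        _, loss = losses.weighted_kappa_loss(
            losses.observed_matrix(a, a),
            losses.expected_matrix(losses.observed_matrix(a, a)),
            losses.weight_matrix(), epsilon=1e-6)
        assert loss == pytest.approx(np.log(1e-6))
        # O == E: kappa = 0, loss = log(1 + eps)
        O = np.outer([1, 2, 3, 2, 2], [2, 1, 1, 3, 3]).astype(float)
        E = losses.expected_matrix(O)
        assert np.allclose(O, E)
        kappa, loss = losses.weighted_kappa_loss(O, E,
                                                 losses.weight_matrix())
        assert kappa == pytest.approx(0.0)
        assert loss == pytest.approx(np.log(1 + 1e-6))

    def test_matches_independent_linear_weighted_kappa(self):
        """1000 random length-30 rating pairs agree with scikit-learn's
        linear-weighted Cohen's kappa to 1e-10."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(1000):
            a = rng.integers(1, 6, size=30)
            b = rng.integers(1, 6, size=30)
            ref = cohen_kappa_score(a, b, labels=[1, 2, 3, 4, 5],
                                    weights="linear")
            assert losses.cohen_kappa(a, b) == pytest.approx(ref,
                                                             abs=1e-10)
            checked += 1
        assert checked == 1000

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(7)
        a = rng.integers(1, 6, size=40)
        b = rng.integers(1, 6, size=40)
        perm = rng.permutation(40)
        assert losses.cohen_kappa(a, b) == pytest.approx(
            losses.cohen_kappa(a[perm], b[perm]))

    def test_loss_strictly_decreasing_in_kappa(self):
        eps = 1e-6
        ks = np.linspace(-0.5, 0.999, 50)
        vals = np.log(1 - ks + eps)
        assert (np.diff(vals) < 0).all()

    def test_degenerate_marginals_error(self):
        O = np.zeros((5, 5))
        O[2, 2] = 10.0  # both raters always say 3: chance term vanishes
        E = losses.expected_matrix(O)
        with pytest.raises(ValueError):
            losses.weighted_kappa_loss(O, E, losses.weight_matrix())


def _record(g=3, o=3, task="cut", **kw):
    return RatingRecord(
        surgery_id="s0",
        gears={k: g for k in GEARS_SUBCATEGORIES},
        osats={k: o for k in OSATS_SUBCATEGORIES},
        task=task, **kw)


class TestMultitaskLoss:
    def _logits(self, records, correct=True, sharp=30.0):
        B = len(records)
        g = np.zeros((B, 6, 5))
        o = np.zeros((B, 7, 5))
        t = np.zeros((B, 3))
        from surgskill.records import TASKS
        for i, r in enumerate(records):
            for h, k in enumerate(GEARS_SUBCATEGORIES):
                g[i, h, r.gears[k] - 1] = sharp
            for h, k in enumerate(OSATS_SUBCATEGORIES):
                o[i, h, r.osats[k] - 1] = sharp
            t[i, TASKS.index(r.task)] = sharp
        return {"gears": nn.Tensor(g), "osats": nn.Tensor(o),
                "task": nn.Tensor(t)}

    def test_near_one_hot_correct_predictions_ce_near_zero(self):
        recs = [_record(2, 4), _record(5, 1, task="recon")]
        loss = losses.multitask_loss(self._logits(recs), recs, "CE")
        assert float(loss.data) < 1e-8

    def test_wk_perfect_agreement_reaches_log_eps_floor(self):
        recs = [_record(1, 2), _record(3, 4), _record(5, 5, task="bolster"),
                _record(2, 1)]
        loss = losses.multitask_loss(self._logits(recs), recs, "WK")
        # 13 subcategory heads each at log(eps); task CE ~ 0
        assert float(loss.data) == pytest.approx(13 * np.log(1e-6), rel=1e-3)

    def test_invalid_records_excluded(self):
        recs = [_record(valid=False)]
        with pytest.raises(ValueError):
            losses.multitask_loss(self._logits(recs), recs, "CE")


class TestMatchingMetrics:
    def test_identical_scores(self):
        s = {k: 3 for k in GEARS_SUBCATEGORIES}
        assert losses.matching_accuracy(s, s) == 1.0
        assert all(v == 0 for v in losses.residuals(s, s).values())

    def test_all_different(self):
        a = {k: 1 for k in GEARS_SUBCATEGORIES}
        b = {k: 5 for k in GEARS_SUBCATEGORIES}
        assert losses.matching_accuracy(a, b) == 0.0

    def test_hand_counted_example(self):
        keys = list(GEARS_SUBCATEGORIES)
        pred = dict(zip(keys, (3, 3, 3, 3, 3, 3)))
        truth = dict(zip(keys, (3, 3, 3, 4, 4, 5)))
        assert losses.matching_accuracy(pred, truth) == pytest.approx(0.5)
        res = losses.residuals(pred, truth)
        assert [res[k] for k in keys] == [0, 0, 0, -1, -1, -2]

    def test_key_mismatch_rejected(self):
        with pytest.raises(KeyError):
            losses.matching_accuracy({"a": 1}, {"b": 1})
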