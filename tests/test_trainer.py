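"""Mean-teacher engine: EMA, loss components, schedules, training loop."""

import numpy as np
import pytest

from ltssl.autodiff import Tensor
from ltssl.data import PerturbProfile
from ltssl.nn import Adam, MLPBackbone
from ltssl.trainer import (ModelPair, TrainConfig, TwoStreamSampler, build_model,
                           consistency_loss, ema_update, rampup_weight,
                           supervised_loss, total_loss, train)


def tiny_pair(decay, seed=3):
    student = MLPBackbone(6, 2, hidden=(4,), proj_dim=3, seed=seed)
    teacher = MLPBackbone(6, 2, hidden=(4,), proj_dim=3, seed=seed + 1)
    return ModelPair(student=student, teacher=teacher, ema_decay=decay)


class TestEMA:
    def test_zero_decay_copies_student(self):
        pair = tiny_pair(0.0)
        ema_update(pair)
        for s, t in zip(pair.student.get_weights(), pair.teacher.get_weights()):
            np.testing.assert_array_equal(s, t)

    def test_unit_decay_freezes_teacher(self):
        pair = tiny_pair(1.0)
        before = pair.teacher.get_weights()
        ema_update(pair)
        for b, t in zip(before, pair.teacher.get_weights()):
            np.testing.assert_array_equal(b, t)

    def test_geometric_recursion_closed_form(self):
        pair = tiny_pair(0.99)
        # constant student = 1, teacher starts at 0
        pair.student.set_weights([np.ones_like(w) for w in pair.student.get_weights()])
        pair.teacher.set_weights([np.zeros_like(w) for w in pair.teacher.get_weights()])
        for _ in range(100):
            ema_update(pair)
        expected = 1 - 0.99**100  # ~0.6340
        for t in pair.teacher.get_weights():
            np.testing.assert_allclose(t, expected, atol=1e-12)

    def test_frozen_student_convergence_within_688_steps(self):
        pair = tiny_pair(0.99)
        steps = int(np.ceil(np.log(1e-3) / np.log(0.99)))  # 688
        for _ in range(steps):
            ema_update(pair)
        gap = max(np.abs(s - t).max() for s, t in
                  zip(pair.student.get_weights(), pair.teacher.get_weights()))
        initial = max(np.abs(s - t).max() for s, t in
                      zip(tiny_pair(0.99).student.get_weights(),
                          tiny_pair(0.99).teacher.get_weights()))
        assert gap < 1e-3 * max(initial, 1.0)

    def test_shape_mismatch_rejected(self):
        pair = ModelPair(student=MLPBackbone(6, 2, hidden=(4,), proj_dim=3),
                         teacher=MLPBackbone(6, 3, hidden=(4,), proj_dim=3),
                         ema_decay=0.9)
        with pytest.raises(ValueError):
            ema_update(pair)


class TestLossComponents:
    def test_supervised_cross_entropy_hand_value(self):
        val = supervised_loss(np.array([[0.9, 0.1]]), np.array([[1, 0]]))
        assert val == pytest.approx(-np.log(0.9), rel=1e-9)

    def test_perfect_prediction_near_zero(self):
        val = supervised_loss(np.array([[1.0, 0.0]]), np.array([[1, 0]]))
        assert val == pytest.approx(0.0, abs=1e-5)

    def test_uniform_predictor_gives_log_C(self):
        C = 7
        p = np.full((3, C), 1 / C)
        y = np.eye(C)[[0, 3, 6]]
        assert supervised_loss(p, y) == pytest.approx(np.log(C), rel=1e-9)

    def test_consistency_identity_and_hand_value(self):
        assert consistency_loss(np.array([[0.3, 0.7]]), np.array([[0.3, 0.7]])) == 0.0
        val = consistency_loss(np.array([[0.2, 0.8]]), np.array([[0.4, 0.6]]))
        assert val == pytest.approx(0.08, rel=1e-12)

    def test_consistency_matches_loop_oracle(self, rng):
        p, q = rng.random((5, 4)), rng.random((5, 4))
        expect = np.mean([sum((p[i, c] - q[i, c]) ** 2 for c in range(4))
                          for i in range(5)])
        assert consistency_loss(p, q) == pytest.approx(expect, abs=1e-8)

    @pytest.mark.parametrize("t, T, expected", [
        (30, 30, 1.0),
        (0, 30, np.exp(-5.0)),
        (15, 30, np.exp(-1.25)),
        (45, 30, 1.0),
    ])
    def test_gaussian_rampup(self, t, T, expected):
        assert rampup_weight(t, T) == pytest.approx(expected, rel=1e-12)

    def test_rampup_rejects_negative_epoch(self):
        with pytest.raises(ValueError):
            rampup_weight(-1, 30)

    def test_total_loss_weighted_sum(self):
        bundle = total_loss(1.0, 2.0, 4.0, 8.0, lambda_t=0.5, beta=0.5, zeta=0.25)
        assert bundle.total == pytest.approx(6.0)
        assert total_loss(0, 0, 0, 0, 0, 0, 0).total == 0.0
        with pytest.raises(ValueError):
            total_loss(1, 1, 1, 1, lambda_t=-0.1, beta=0.5, zeta=0.25)

    def test_default_unlabeled_loss_weights(self):
        cfg = TrainConfig()
        assert cfg.beta == 0.5 and cfg.zeta == 0.25


class TestSampler:
    def test_fixed_composition_and_unlabeled_coverage(self, rng):
        lab = np.arange(10)
        unlab = np.arange(100, 172)
        sampler = TwoStreamSampler(lab, unlab, 4, 12, rng)
        seen = []
        for lab_b, unlab_b in sampler.epoch_batches():
            assert lab_b.size == 4 and unlab_b.size == 12
            assert np.isin(lab_b, lab).all() and np.isin(unlab_b, unlab).all()
            seen.append(unlab_b)
        assert len(seen) == 6
        assert np.unique(np.concatenate(seen)).size == 72

    def test_labeled_only_mode(self, rng):
        sampler = TwoStreamSampler(np.arange(9), np.array([]), 3, 12, rng,
                                   use_unlabeled=False)
        batches = list(sampler.epoch_batches())
        assert len(batches) == 3
        assert all(u.size == 0 for _, u in batches)


class TestTrainLoop:
    def test_smoke_run_finite_and_teacher_differs(self, tiny_dataset, tiny_split):
        cfg = TrainConfig(epochs=2, ramp_epochs=2, capr_start_epoch=1,
                          hidden=(32,), proj_dim=8, seed=0)
        res = train(tiny_dataset, tiny_split, cfg)
        assert all(np.isfinite(rec["total"]) for rec in res.history)
        assert len(res.history) == 2
        diffs = [np.abs(s - t).max() for s, t in
                 zip(res.pair.student.get_weights(), res.pair.teacher.get_weights())]
        assert max(diffs) > 0
        assert res.final_metrics is not None

    def test_loss_ledger_conservation(self, tiny_dataset, tiny_split):
        cfg = TrainConfig(epochs=2, ramp_epochs=2, capr_start_epoch=0,
                          hidden=(16,), proj_dim=4, seed=1)
        res = train(tiny_dataset, tiny_split, cfg)
        for rec in res.step_log:
            recomputed = (rec["l_sup"] + rec["lambda_t"] * rec["l_cs"]
                          + rec["beta"] * rec["l_scl"] + rec["zeta"] * rec["l_pl"])
            assert rec["total"] == pytest.approx(recomputed, abs=1e-9)

    def test_capr_inactive_before_start_epoch(self, tiny_dataset, tiny_split):
        cfg = TrainConfig(epochs=3, ramp_epochs=2, capr_start_epoch=2,
                          hidden=(16,), proj_dim=4, seed=2)
        res = train(tiny_dataset, tiny_split, cfg)
        assert not res.history[0]["capr_active"]
        assert not res.history[1]["capr_active"]
        assert res.history[2]["capr_active"]

    def test_determinism_given_seed(self, tiny_dataset, tiny_split):
        cfg = TrainConfig(epochs=1, hidden=(16,), proj_dim=4, seed=5)
        r1 = train(tiny_dataset, tiny_split, cfg)
        r2 = train(tiny_dataset, tiny_split, cfg)
        for a, b in zip(r1.pair.student.get_weights(), r2.pair.student.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_degenerate_config_matches_plain_supervised_trainer(
            self, tiny_dataset, tiny_split):
        """All unlabeled machinery off == an independently written supervised
        loop with the same init, sampling and optimizer streams."""
        cfg = TrainConfig(epochs=2, use_consistency=False, use_sde=False,
                          use_capr=False, perturb=PerturbProfile.zero(),
                          hidden=(16,), proj_dim=4, seed=7)
        res = train(tiny_dataset, tiny_split, cfg)

        seeds = np.random.SeedSequence(7).generate_state(4) % (2**31)
        input_dim = int(np.prod(tiny_dataset.image_shape))
        model = build_model(input_dim, tiny_dataset.n_classes, cfg, int(seeds[0]))
        sampler = TwoStreamSampler(
            tiny_split.labeled, tiny_split.unlabeled, cfg.labeled_per_batch,
            cfg.unlabeled_per_batch, np.random.default_rng(int(seeds[1])),
            use_unlabeled=False)
        opt = Adam(model.parameters(), lr=cfg.learning_rate)
        flat = tiny_dataset.X.reshape(len(tiny_dataset.X), -1)
        oracle_losses = []
        for epoch in range(cfg.epochs):
            opt.lr = cfg.learning_rate * cfg.lr_decay**epoch
            for lab_idx, _ in sampler.epoch_batches():
                logits, _ = model.forward(Tensor(flat[lab_idx]))
                p = logits.softmax().clip(1e-7, 1 - 1e-7)
                y = Tensor(tiny_dataset.Y[lab_idx].astype(float))
                loss = -(y * p.log()).sum(axis=1).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                oracle_losses.append(float(loss.data))

        trainer_losses = [rec["l_sup"] for rec in res.step_log]
        np.testing.assert_allclose(trainer_losses, oracle_losses, rtol=1e-12)

    def test_empty_labeled_set_rejected(self, tiny_dataset, tiny_split):
        from ltssl.data import LabeledSplit
        empty = LabeledSplit(labeled=np.array([], dtype=int),
                             unlabeled=tiny_split.unlabeled, label_fraction=0.0)
        with pytest.raises(ValueError):
            train(tiny_dataset, empty, TrainConfig(epochs=1))


class TestCheckpoint:
    def test_roundtrip_preserves_parameters(self, tiny_dataset, tiny_split, tmp_path):
        from ltssl.trainer import load_checkpoint, save_checkpoint
        cfg = TrainConfig(epochs=1, hidden=(16,), proj_dim=4, seed=9)
        res = train(tiny_dataset, tiny_split, cfg)
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(res, path)
        pair = load_checkpoint(path, int(np.prod(tiny_dataset.image_shape)),
                               tiny_dataset.n_classes)
        for a, b in zip(res.pair.student.get_weights(), pair.student.get_weights()):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(res.pair.teacher.get_weights(), pair.teacher.get_weights()):
            np.testing.assert_array_equal(a, b)
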