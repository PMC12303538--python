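"""Image pool, masked loss, training loop and checkpoint selection."""

import numpy as np
import pytest

from glomseg import (CheckpointRecord, DynamicSegModel, ImagePool,
                     LabeledPatch, TrainConfig, masked_task_loss,
                     select_best, synthetic_catalog, train)
from glomseg.nn import Tensor


def _patch(class_index=0, size=16, fill=0.5, patient="p0", domain="source",
           seed=None):
    rng = np.random.default_rng(seed if seed is not None else class_index)
    img = np.full((size, size, 3), fill, dtype=np.float32)
    mask = np.zeros((size, size), dtype=np.uint8)
    c = size // 2
    r = size // 4
    yy, xx = np.mgrid[0:size, 0:size]
    mask[(yy - c) ** 2 + (xx - c) ** 2 <= r * r] = 1
    img[mask == 1] = rng.random()
    return LabeledPatch(image=img, mask=mask, class_index=class_index,
                        domain=domain, patient_id=patient)


class TestImagePool:
    def test_batch_emitted_when_buffer_exceeds_batch_size(self):
        pool = ImagePool(capacity=14, batch_size=4, seed=0)
        for i in range(4):
            assert pool.push(_patch(i)) is None
        batch = pool.push(_patch(4))
        assert batch is not None and len(batch) == 4
        assert len(pool.buffer) == 1

    def test_conservation_over_many_pushes(self):
        pool = ImagePool(capacity=14, batch_size=4, seed=1)
        drawn = 0
        for i in range(1000):
            batch = pool.push(_patch(i % 14))
            if batch:
                drawn += len(batch)
            assert pool.n_pushed - drawn == len(pool.buffer)
            assert len(pool.buffer) <= pool.capacity
        assert drawn == pool.n_drawn

    def test_seeded_draws_reproducible(self):
        def run(seed):
            pool = ImagePool(capacity=10, batch_size=4, seed=seed)
            order = []
            for i in range(50):
                batch = pool.push(_patch(i % 10, patient=f"p{i}", seed=i))
                if batch:
                    order.append([p.patient_id for p in batch])
            return order
        assert run(9) == run(9)
        assert run(9) != run(10)

    def test_batch_larger_than_capacity_rejected(self):
        with pytest.raises(ValueError):
            ImagePool(capacity=3, batch_size=4)


class TestMaskedTaskLoss:
    def test_perfect_saturated_prediction_near_zero(self):
        mask = np.zeros((1, 1, 8, 8), dtype=np.float64)
        mask[:, :, 2:6, 2:6] = 1
        logits = np.where(mask == 1, 40.0, -40.0)
        loss = masked_task_loss(Tensor(logits), mask)
        assert float(loss.data) < 1e-3

    def test_zero_logits_bce_is_ln2_per_pixel(self):
        mask = np.ones((1, 1, 4, 4))
        loss = masked_task_loss(Tensor(np.zeros((1, 1, 4, 4))), mask,
                                dice_weight=0.0, bce_weight=1.0)
        assert float(loss.data) == pytest.approx(np.log(2))

    def test_soft_dice_hand_case(self):
        # probs {1,1,0,0} vs target {1,0,1,0}, smoothing 1:
        # 1 - (2*1+1)/(2+2+1) = 0.4
        logits = np.array([[[60.0, 60.0, -60.0, -60.0]]])
        target = np.array([[[1.0, 0.0, 1.0, 0.0]]])
        loss = masked_task_loss(Tensor(logits), target, dice_weight=1.0,
                                bce_weight=0.0, smooth=1.0)
        assert float(loss.data) == pytest.approx(0.4, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            masked_task_loss(Tensor(np.zeros((1, 1, 4, 4))),
                             np.zeros((1, 1, 5, 5)))

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(dice_weight=0.0, bce_weight=0.0)


class TestGradientIsolation:
    def test_batch_loss_equals_mean_of_per_sample_losses(self,
                                                         tiny_backbone_cfg,
                                                         tiny_head):
        """Partial-label soundness: the batched masked loss is exactly the
        mean of independently computed per-sample masked losses."""
        model = DynamicSegModel(3, tiny_backbone_cfg, tiny_head,
                                np.random.default_rng(0))
        patches = [_patch(k, seed=k) for k in range(4)]
        patches[3] = _patch(0, seed=7)
        x = np.stack([p.image.transpose(2, 0, 1) for p in patches])
        t = np.stack([p.mask for p in patches])[:, None].astype(np.float64)
        idx = [min(p.class_index, 2) for p in patches]
        batch_loss = float(masked_task_loss(
            model.forward_batch(Tensor(x), idx), t).data)
        singles = [float(masked_task_loss(
            model.forward_batch(Tensor(x[k:k + 1]), [idx[k]]),
            t[k:k + 1]).data) for k in range(4)]
        assert batch_loss == pytest.approx(np.mean(singles), rel=1e-4)


class TestCheckpointSelection:
    def test_mean_consistency_enforced(self):
        with pytest.raises(ValueError):
            CheckpointRecord(1, {"a": 0.5, "b": 0.7}, 0.9)

    def test_ties_resolve_to_earliest_epoch(self):
        records = [CheckpointRecord(1, {"a": 0.6}, 0.6),
                   CheckpointRecord(2, {"a": 0.8}, 0.8),
                   CheckpointRecord(3, {"a": 0.8}, 0.8)]
        assert select_best(records) == 2


@pytest.fixture(scope="module")
def toy_problem():
    """Two-class toy: a bright centered disk (class 0) and its complement
    ring (class 1); learnable by color in a few dozen steps."""
    patches = []
    for i in range(12):
        p = _patch(i % 2, size=16, patient=f"p{i // 2}", seed=100 + i)
        patches.append(p)
    return patches


class TestTrainLoop:
    def test_two_epochs_produce_two_records_and_best(self, toy_problem,
                                                     tiny_backbone_cfg,
                                                     tiny_head):
        cat = synthetic_catalog()
        model = DynamicSegModel(cat.num_classes, tiny_backbone_cfg, tiny_head,
                                np.random.default_rng(1))
        cfg = TrainConfig(epochs=2, seed=3)
        result = train(model, toy_problem[:8], toy_problem[8:], cat, cfg)
        assert len(result.records) == 2
        best = max(r.mean_dice for r in result.records)
        assert result.records[result.best_epoch - 1].mean_dice == best

    def test_loss_decreases_on_learnable_toy(self, toy_problem,
                                             tiny_backbone_cfg, tiny_head):
        cat = synthetic_catalog()
        model = DynamicSegModel(cat.num_classes, tiny_backbone_cfg, tiny_head,
                                np.random.default_rng(2))
        cfg = TrainConfig(epochs=25, seed=4)
        result = train(model, toy_problem[:8], toy_problem[8:], cat, cfg)
        first = np.mean(result.loss_history[:5])
        last = np.mean(result.loss_history[-5:])
        assert last < first

    def test_fixed_seed_reproduces_loss_trajectory(self, toy_problem,
                                                   tiny_backbone_cfg,
                                                   tiny_head):
        cat = synthetic_catalog()

        def run():
            model = DynamicSegModel(cat.num_classes, tiny_backbone_cfg,
                                    tiny_head, np.random.default_rng(5))
            cfg = TrainConfig(epochs=2, seed=6)
            return train(model, toy_problem[:8], toy_problem[8:], cat,
                         cfg).loss_history
        assert run() == run()

    def test_empty_sets_rejected(self, toy_problem, tiny_backbone_cfg,
                                 tiny_head):
        cat = synthetic_catalog()
        model = DynamicSegModel(cat.num_classes, tiny_backbone_cfg, tiny_head,
                                np.random.default_rng(0))
        with pytest.raises(ValueError):
            train(model, [], toy_problem[8:], cat, TrainConfig(epochs=1))

    def test_class_absent_from_validation_warns(self, toy_problem,
                                                tiny_backbone_cfg, tiny_head):
        cat = synthetic_catalog()
        model = DynamicSegModel(cat.num_classes, tiny_backbone_cfg, tiny_head,
                                np.random.default_rng(0))
        val_only_class0 = [p for p in toy_problem[8:] if p.class_index == 0]
        with pytest.warns(UserWarning, match="missing from validation"):
            train(model, toy_problem[:8], val_only_class0, cat,
                  TrainConfig(epochs=1, seed=0))
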