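"""Dice coefficient, partial-label evaluation, and the multi-head baseline."""

import numpy as np
import pytest

from glomseg import (BaselineModel, LabeledPatch, baseline_forward, dice,
                     evaluate, synthetic_catalog)
from glomseg.nn import Adam, Tensor
from glomseg.training import masked_task_loss


def brute_force_dice(p, g):
    p_set = {tuple(ix) for ix in np.argwhere(np.asarray(p, dtype=bool))}
    g_set = {tuple(ix) for ix in np.argwhere(np.asarray(g, dtype=bool))}
    if not p_set and not g_set:
        return 1.0
    return 2.0 * len(p_set & g_set) / (len(p_set) + len(g_set))


class TestDice:
    def test_hand_cases(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, :] = 1
        assert dice(a, a) == 1.0
        b = np.zeros((4, 4), dtype=np.uint8)
        b[1, :] = 1
        assert dice(a, b) == 0.0
        p = np.zeros(8, dtype=np.uint8)
        p[:4] = 1
        g = np.zeros(8, dtype=np.uint8)
        g[2:4] = 1
        assert dice(p, g) == pytest.approx(2 / 3)

    def test_degenerate_conventions(self):
        empty = np.zeros((3, 3), dtype=np.uint8)
        full = np.ones((3, 3), dtype=np.uint8)
        assert dice(empty, empty) == 1.0
        assert dice(empty, full) == 0.0
        assert dice(full, empty) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_set_arithmetic_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            p = (rng.random((6, 6)) > rng.random()).astype(np.uint8)
            g = (rng.random((6, 6)) > rng.random()).astype(np.uint8)
            assert dice(p, g) == pytest.approx(brute_force_dice(p, g))

    def test_symmetry(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            p = (rng.random((5, 5)) > 0.5).astype(np.uint8)
            g = (rng.random((5, 5)) > 0.5).astype(np.uint8)
            assert dice(p, g) == dice(g, p)

    def test_relation_to_symmetric_difference(self):
        """1 - Dice never exceeds twice the normalized symmetric
        difference |PΔG| / (|P| + |G|)."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = (rng.random((6, 6)) > 0.4).astype(np.uint8)
            g = (rng.random((6, 6)) > 0.6).astype(np.uint8)
            total = p.sum() + g.sum()
            if total == 0:
                continue
            sym = np.logical_xor(p, g).sum() / total
            assert 1.0 - dice(p, g) <= 2.0 * sym + 1e-12

    def test_shape_mismatch_and_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="binary"):
            dice(np.full((2, 2), 3), np.zeros((2, 2)))


class _OracleModel:
    """Predicts each sample's ground truth exactly (for evaluate tests)."""

    def __init__(self, lookup):
        self.lookup = lookup

    def predict_batch(self, images, class_indices):
        out = []
        for img, k in zip(images, class_indices):
            out.append(self.lookup[(img.tobytes(), k)].astype(np.float64))
        return np.stack(out)


def _dataset(scores_by_class, size=8):
    """Build patches + a model whose per-sample Dice hits given targets."""
    patches, lookup = [], {}
    rng = np.random.default_rng(0)
    for ci, sample_specs in scores_by_class.items():
        for j, frac in enumerate(sample_specs):
            img = rng.random((size, size, 3)).astype(np.float32)
            gt = np.zeros((size, size), dtype=np.uint8)
            gt[:4, :] = 1   # 32 pixels
            pred = np.zeros((size, size), dtype=np.float64)
            n_hit = int(round(32 * frac))
            pred.flat[np.flatnonzero(gt.ravel())[:n_hit]] = 1.0
            patches.append(LabeledPatch(image=img, mask=gt, class_index=ci,
                                        domain="source",
                                        patient_id=f"p{ci}_{j}"))
            lookup[(img.transpose(2, 0, 1).astype(np.float32).tobytes(),
                    ci)] = pred
    return patches, _OracleModel(lookup)


class TestEvaluate:
    def test_perfect_predictions_score_one(self, catalog):
        patches, model = _dataset({0: [1.0, 1.0], 1: [1.0]})
        with pytest.warns(UserWarning):
            result = evaluate(model, patches, catalog)
        assert result.mean == 1.0
        assert all(v == 1.0 for v in result.per_class.values())

    def test_mean_is_over_classes_not_samples(self, catalog):
        # class 0: three samples at Dice 0.8; class 1: one sample at 0.6 →
        # class mean 0.7, sample-weighted mean would be 0.75
        def frac_for(target):  # pred ⊆ gt so Dice = 2n/(n+32)
            return target / (2 - target)
        patches, model = _dataset({0: [frac_for(0.8)] * 3,
                                   1: [frac_for(0.6)]})
        with pytest.warns(UserWarning):
            result = evaluate(model, patches, catalog)
        assert result.per_class["cap"] == pytest.approx(0.8, abs=0.02)
        assert result.per_class["tuft"] == pytest.approx(0.6, abs=0.02)
        assert result.mean == pytest.approx(
            (result.per_class["cap"] + result.per_class["tuft"]) / 2)

    def test_matches_brute_force_recomputation(self, catalog,
                                               phantom_batch,
                                               tiny_backbone_cfg):
        model = BaselineModel(catalog.num_classes, tiny_backbone_cfg,
                              np.random.default_rng(3))
        patches = [s.patch for s in phantom_batch]
        with pytest.warns(UserWarning):
            result = evaluate(model, patches, catalog)
        by_class = {}
        for p in patches:
            prob = model.predict_batch(
                p.image.transpose(2, 0, 1)[None], [p.class_index])[0]
            by_class.setdefault(p.class_index, []).append(
                dice((prob > 0.5).astype(np.uint8), p.mask))
        for ci, vals in by_class.items():
            name = catalog.classes[ci].name
            assert result.per_class[name] == pytest.approx(np.mean(vals))

    def test_deterministic(self, catalog, phantom_batch, tiny_backbone_cfg):
        model = BaselineModel(catalog.num_classes, tiny_backbone_cfg,
                              np.random.default_rng(3))
        patches = [s.patch for s in phantom_batch]
        with pytest.warns(UserWarning):
            r1 = evaluate(model, patches, catalog)
        with pytest.warns(UserWarning):
            r2 = evaluate(model, patches, catalog)
        assert r1.per_class == r2.per_class


class TestBaselineModel:
    def test_zero_head_gives_half_everywhere(self, catalog,
                                             tiny_backbone_cfg):
        model = BaselineModel(catalog.num_classes, tiny_backbone_cfg,
                              np.random.default_rng(0))
        model.head.weight.data[:] = 0
        model.head.bias.data[:] = 0
        maps = baseline_forward(np.zeros((16, 16, 3), dtype=np.float32),
                                model)
        assert len(maps) == catalog.num_classes
        for m in maps:
            np.testing.assert_allclose(m.probabilities, 0.5)

    def test_output_shapes(self, catalog, tiny_backbone_cfg):
        model = BaselineModel(catalog.num_classes, tiny_backbone_cfg,
                              np.random.default_rng(1))
        maps = baseline_forward(
            np.random.default_rng(2).random((16, 16, 3)).astype(np.float32),
            model)
        assert all(m.probabilities.shape == (16, 16) for m in maps)

    def test_trains_on_toy_problem(self, tiny_backbone_cfg):
        rng = np.random.default_rng(4)
        imgs = np.full((6, 3, 16, 16), 0.1, dtype=np.float32)
        masks = np.zeros((6, 1, 16, 16), dtype=np.float32)
        for i in range(6):
            cy, cx = rng.integers(5, 11, 2)
            yy, xx = np.mgrid[0:16, 0:16]
            m = (yy - cy) ** 2 + (xx - cx) ** 2 <= 9
            masks[i, 0][m] = 1
            imgs[i, :, m] = 0.9
        model = BaselineModel(2, tiny_backbone_cfg, np.random.default_rng(5))
        opt = Adam(model.parameters(), lr=1e-3)
        losses = []
        for _ in range(30):
            lg = model.forward_batch(Tensor(imgs), [0] * 6)
            loss = masked_task_loss(lg, masks)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        assert losses[-1] < losses[0]
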