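"""Controller and dynamic head: parameter counts, oracle equivalence,
class conditioning, and the end-to-end composition."""

import numpy as np
import pytest

from glomseg import (BackboneConfig, Controller, DynamicSegModel, HeadSpec,
                     KernelParams, controller_forward, dynamic_head_forward,
                     kernel_param_count)
from glomseg.dynamic_head import dynamic_head_apply
from glomseg.nn import Tensor


def brute_force_head(decoder_feature: np.ndarray,
                     kernels: KernelParams) -> np.ndarray:
    """Independent oracle: at every pixel, apply the three generated
    matrix–vector products one pixel at a time."""
    d, h, w = decoder_feature.shape
    (w1, b1), (w2, b2), (w3, b3) = kernels.layers()
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            v = decoder_feature[:, i, j]
            v = np.maximum(w1 @ v + b1, 0.0)
            v = np.maximum(w2 @ v + b2, 0.0)
            out[i, j] = (w3 @ v + b3)[0]
    return out


class TestParameterCount:
    def test_reference_configuration(self):
        assert kernel_param_count(8, HeadSpec((8, 8, 1))) == 153

    @pytest.mark.parametrize("d", [1, 2, 4, 8])
    @pytest.mark.parametrize("c1", [1, 2, 4, 8])
    @pytest.mark.parametrize("c2", [1, 2, 4, 8])
    def test_closed_form_over_grid(self, d, c1, c2):
        spec = HeadSpec((c1, c2, 1))
        n = kernel_param_count(d, spec)
        assert n == (d * c1 + c1) + (c1 * c2 + c2) + (c2 + 1)
        flat = np.zeros(n)
        kp = KernelParams(flat=flat, decoder_channels=d, spec=spec)
        total = sum(wb.size for pair in kp.layers() for wb in pair)
        assert total == n

    def test_controller_output_length_matches(self):
        for d in (2, 4, 8):
            spec = HeadSpec((4, 4, 1))
            ctrl = Controller(bottleneck_channels=16, num_classes=5,
                              decoder_channels=d, spec=spec,
                              rng=np.random.default_rng(0))
            f = np.random.default_rng(1).random((16, 2, 2))
            kp = controller_forward(f, np.eye(5)[1], ctrl)
            assert kp.flat.size == kernel_param_count(d, spec)

    def test_head_spec_constraints(self):
        with pytest.raises(ValueError):
            HeadSpec((4, 4, 2))
        with pytest.raises(ValueError):
            HeadSpec((0, 4, 1))


class TestController:
    def test_zero_controller_emits_zero_kernels(self):
        ctrl = Controller(8, 3, 4, HeadSpec((4, 4, 1)),
                          np.random.default_rng(0))
        ctrl.fc.weight.data[:] = 0
        ctrl.fc.bias.data[:] = 0
        f = np.random.default_rng(2).random((8, 4, 4))
        kp = controller_forward(f, np.eye(3)[0], ctrl)
        np.testing.assert_array_equal(kp.flat, 0)

    def test_distinct_tasks_give_distinct_kernels(self):
        ctrl = Controller(8, 3, 4, HeadSpec((4, 4, 1)),
                          np.random.default_rng(3))
        f = np.random.default_rng(4).random((8, 4, 4))
        kp0 = controller_forward(f, np.eye(3)[0], ctrl)
        kp1 = controller_forward(f, np.eye(3)[1], ctrl)
        assert np.abs(kp0.flat - kp1.flat).max() > 0

    def test_mismatched_task_length_raises(self):
        ctrl = Controller(8, 3, 4, HeadSpec((4, 4, 1)),
                          np.random.default_rng(0))
        with pytest.raises(ValueError, match="m"):
            controller_forward(np.zeros((8, 2, 2)), np.eye(4)[0], ctrl)


class TestDynamicHeadForward:
    def test_zero_kernels_give_half_probability(self):
        spec = HeadSpec((4, 4, 1))
        kp = KernelParams(np.zeros(kernel_param_count(3, spec)), 3, spec)
        pm = dynamic_head_forward(np.random.default_rng(0).random((3, 5, 5)),
                                  kp)
        np.testing.assert_allclose(pm.probabilities, 0.5)
        np.testing.assert_allclose(pm.logits, 0.0)

    def test_hand_computed_identity_chain(self):
        # D=1, widths (1,1,1), unit weights, zero biases: positives pass
        # both rectifiers unchanged, so logit == input value
        spec = HeadSpec((1, 1, 1))
        flat = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        kp = KernelParams(flat, 1, spec)
        m = np.full((1, 2, 2), 2.0)
        pm = dynamic_head_forward(m, kp)
        np.testing.assert_allclose(pm.logits, 2.0)
        np.testing.assert_allclose(pm.probabilities,
                                   1 / (1 + np.exp(-2.0)))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_pixel_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 9))
        spec = HeadSpec((int(rng.integers(1, 9)), int(rng.integers(1, 9)), 1))
        m = rng.standard_normal((d, 4, 4))
        kp = KernelParams(rng.standard_normal(kernel_param_count(d, spec)),
                          d, spec)
        pm = dynamic_head_forward(m, kp)
        np.testing.assert_allclose(pm.logits, brute_force_head(m, kp),
                                   atol=1e-5)

    def test_batched_apply_equals_single_sample_path(self):
        rng = np.random.default_rng(11)
        spec = HeadSpec((4, 4, 1))
        d = 3
        n = kernel_param_count(d, spec)
        m = rng.standard_normal((2, d, 5, 5))
        om = rng.standard_normal((2, n))
        out = dynamic_head_apply(Tensor(m), Tensor(om), d, spec)
        for k in range(2):
            kp = KernelParams(om[k], d, spec)
            np.testing.assert_allclose(out.data[k, 0],
                                       dynamic_head_forward(m[k], kp).logits,
                                       atol=1e-6)

    def test_channel_mismatch_raises(self):
        spec = HeadSpec((2, 2, 1))
        kp = KernelParams(np.zeros(kernel_param_count(4, spec)), 4, spec)
        with pytest.raises(ValueError, match="channels"):
            dynamic_head_forward(np.zeros((3, 4, 4)), kp)

    def test_nonfinite_kernels_rejected(self):
        spec = HeadSpec((2, 2, 1))
        flat = np.zeros(kernel_param_count(2, spec))
        flat[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            KernelParams(flat, 2, spec)


@pytest.fixture(scope="module")
def model(tiny_backbone_cfg, tiny_head):
    return DynamicSegModel(num_classes=4, backbone_config=tiny_backbone_cfg,
                           head_spec=tiny_head, rng=np.random.default_rng(5))


class TestSegmentClass:
    def test_zeroed_controller_gives_flat_half_maps(self, model):
        state = model.state_dict()
        model.controller.fc.weight.data[:] = 0
        model.controller.fc.bias.data[:] = 0
        img = np.random.default_rng(6).random((16, 16, 3)).astype(np.float32)
        for k in range(4):
            pm = model.segment_class(img, k)
            np.testing.assert_allclose(pm.probabilities, 0.5)
        model.load_state_dict(state)

    def test_repeat_calls_identical(self, model):
        img = np.random.default_rng(7).random((16, 16, 3)).astype(np.float32)
        a = model.segment_class(img, 1)
        b = model.segment_class(img, 1)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)

    def test_class_conditioning_changes_maps(self, model):
        """A randomly initialized controller must produce genuinely
        different maps for different task vectors on the same image."""
        img = np.random.default_rng(8).random((16, 16, 3)).astype(np.float32)
        m0 = model.segment_class(img, 0).probabilities
        diffs = [np.abs(model.segment_class(img, k).probabilities - m0).mean()
                 for k in range(1, 4)]
        assert min(diffs) > 0

    def test_all_class_query_returns_m_maps_that_may_overlap(self, model):
        img = np.random.default_rng(9).random((16, 16, 3)).astype(np.float32)
        maps = model.segment_all_classes(img)
        assert len(maps) == 4
        # structural multi-label capability: force two classes to fire by
        # loading constant-positive kernels through a zeroed controller
        model_state = model.state_dict()
        model.controller.fc.weight.data[:] = 0
        model.controller.fc.bias.data[:] = 1.0
        maps = model.segment_all_classes(img)
        overlap = maps[0].binarize() & maps[1].binarize()
        assert overlap.sum() > 0
        model.load_state_dict(model_state)

    def test_invalid_class_index_propagates(self, model):
        img = np.zeros((16, 16, 3), dtype=np.float32)
        with pytest.raises(ValueError, match="4"):
            model.segment_class(img, 4)
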