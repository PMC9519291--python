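"""Fusion algebra, attention range, baseline degeneration, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cariesctx.model import (
    ContextAwareModel,
    ModelConfig,
    fuse,
    load_checkpoint,
    pool_neighbors,
    save_checkpoint,
)


@pytest.fixture(scope="module")
def tiny_model():
    cfg = ModelConfig(backbone="tiny", d=32, h=16, k_neighbors=3, input_side=32, init_seed=3)
    return ContextAwareModel(cfg)


class TestPooling:
    def test_elementwise_mean(self):
        np.testing.assert_allclose(pool_neighbors([[1, 3], [3, 5]]), [2, 4])

    def test_single_element_identity(self):
        np.testing.assert_allclose(pool_neighbors([[7.0, -1.0]]), [7.0, -1.0])

    def test_permutation_invariance(self, rng):
        reps = rng.standard_normal((5, 8))
        perm = rng.permutation(5)
        np.testing.assert_allclose(pool_neighbors(reps), pool_neighbors(reps[perm]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_neighbors(np.zeros((0, 4)))


class TestFuse:
    def test_alpha_one_returns_current(self, rng):
        r_c, r_a = rng.standard_normal((2, 6))
        np.testing.assert_allclose(fuse(r_c, r_a, 1.0), r_c)

    def test_alpha_zero_returns_context(self, rng):
        r_c, r_a = rng.standard_normal((2, 6))
        np.testing.assert_allclose(fuse(r_c, r_a, 0.0), r_a)

    def test_midpoint(self):
        np.testing.assert_allclose(fuse([2.0, 0.0], [0.0, 2.0], 0.5), [1.0, 1.0])

    def test_shape_mismatch_and_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            fuse([1.0, 2.0], [1.0], 0.5)
        with pytest.raises(ValueError):
            fuse([1.0], [1.0], 1.5)


class TestAttention:
    def test_zero_parameters_give_half(self):
        cfg = ModelConfig(backbone="tiny", d=8, h=4, input_side=16)
        m = ContextAwareModel(cfg)
        for k, v in m.fusion.params().items():
            v[...] = 0.0
        a = m.attention_weight(np.ones((1, 8)), np.zeros((1, 8)))
        assert a[0] == pytest.approx(0.5)

    def test_large_output_bias_saturates_towards_one(self):
        cfg = ModelConfig(backbone="tiny", d=8, h=4, input_side=16)
        m = ContextAwareModel(cfg)
        p = m.fusion.params()
        p["W2"][...] = 0.0
        p["b2"][...] = 10.0
        a = m.attention_weight(np.zeros((1, 8)), np.zeros((1, 8)))
        assert a[0] == pytest.approx(1.0 / (1.0 + np.exp(-10.0)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_alpha_always_in_open_unit_interval(self, seed):
        cfg = ModelConfig(backbone="tiny", d=8, h=4, input_side=16)
        m = ContextAwareModel(cfg)
        r = np.random.default_rng(seed).standard_normal((4, 8)) * 10
        a = m.attention_weight(r, -r)
        assert np.all((a > 0) & (a < 1))

    def test_non_finite_inputs_rejected(self, tiny_model):
        bad = np.full((1, 32), np.nan)
        with pytest.raises(ValueError):
            tiny_model.attention_weight(bad, bad)


class TestClassifier:
    def test_zero_weights_give_uniform(self):
        cfg = ModelConfig(backbone="tiny", d=8, h=4, input_side=16)
        m = ContextAwareModel(cfg)
        for v in m.classifier.params().values():
            v[...] = 0.0
        np.testing.assert_allclose(m.classify(np.ones((3, 8))), 0.5)

    def test_probabilities_sum_to_one(self, tiny_model, rng):
        p = tiny_model.classify(rng.standard_normal((10, 32)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p > 0)

    def test_logit_shift_invariance(self, tiny_model, rng):
        r = rng.standard_normal((4, 32)).astype(np.float32)
        p1 = tiny_model.classify(r)
        tiny_model.classifier.params()["b"][...] += 3.0
        p2 = tiny_model.classify(r)
        tiny_model.classifier.params()["b"][...] -= 3.0
        np.testing.assert_allclose(p1, p2, atol=1e-5)


class TestForward:
    def test_backbone_weight_sharing_across_branches(self, tiny_model, rng):
        img = rng.random((32, 32), dtype=np.float32)
        r1 = tiny_model.backbone_forward(img)
        r2 = tiny_model.backbone_forward(img)
        np.testing.assert_array_equal(r1, r2)
        assert r1.shape == (1, 32)

    def test_neighbor_order_invariance(self, tiny_model, rng):
        cur = rng.random((32, 32), dtype=np.float32)
        nbs = [rng.random((32, 32), dtype=np.float32) for _ in range(3)]
        p1 = tiny_model.forward_single(cur, nbs)
        p2 = tiny_model.forward_single(cur, nbs[::-1])
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_no_neighbors_bypasses_fusion_bit_for_bit(self, rng):
        """Baseline degeneration: with no usable context the context model's
        output equals the k=0 model with identical weights, exactly."""
        cfg3 = ModelConfig(backbone="tiny", d=32, h=16, k_neighbors=3, input_side=32, init_seed=5)
        cfg0 = ModelConfig(backbone="tiny", d=32, h=16, k_neighbors=0, input_side=32, init_seed=5)
        m3 = ContextAwareModel(cfg3)
        m0 = ContextAwareModel(cfg0)
        m0.load_state(m3.state())  # same weights
        x = rng.random((4, 32, 32), dtype=np.float32)
        np.testing.assert_array_equal(m3.predict_proba(x), m0.predict_proba(x))

    def test_alpha_one_reproduces_baseline_prediction(self, rng):
        cfg = ModelConfig(backbone="tiny", d=16, h=8, k_neighbors=3, input_side=16, init_seed=2)
        m = ContextAwareModel(cfg)
        # saturate the attention at alpha ~ 1
        m.fusion.params()["W2"][...] = 0.0
        m.fusion.params()["b2"][...] = 500.0
        x = rng.random((2, 16, 16), dtype=np.float32)
        nb = rng.random((5, 16, 16), dtype=np.float32)
        seg = np.array([0, 0, 0, 1, 1])
        with_ctx = m.predict_proba(x, nb, seg)
        without = m.predict_proba(x)
        np.testing.assert_allclose(with_ctx, without, atol=1e-6)

    def test_gradients_reach_every_parameter(self, rng):
        cfg = ModelConfig(backbone="tiny", d=16, h=8, k_neighbors=3, input_side=16, init_seed=1)
        m = ContextAwareModel(cfg)
        x = rng.random((6, 16, 16), dtype=np.float32)
        nb = rng.random((12, 16, 16), dtype=np.float32)
        seg = np.repeat(np.arange(6), 2)
        m.forward_batch(x, nb, seg, train=True)
        m.loss_and_backward(np.array([0, 1, 0, 1, 1, 0]))
        for name, g in m.grads().items():
            assert np.any(g != 0), f"zero gradient for {name}"

    def test_extra_parameter_count_is_fusion_only(self):
        d, h = 32, 16
        cfg = ModelConfig(backbone="tiny", d=d, h=h, k_neighbors=3, input_side=32)
        m = ContextAwareModel(cfg)
        assert m.extra_params_over_baseline() == h * 2 * d + h + h + 1

    def test_wrong_input_side_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError):
            tiny_model.backbone_forward(rng.random((1, 24, 24)))


def test_checkpoint_round_trip(tmp_path, tiny_model, rng):
    x = rng.random((2, 32, 32), dtype=np.float32)
    want = tiny_model.predict_proba(x)
    path = tmp_path / "model.npz"
    save_checkpoint(tiny_model, path, meta={"note": "test"})
    back, meta = load_checkpoint(path)
    assert meta == {"note": "test"}
    assert back.config == tiny_model.config
    np.testing.assert_array_equal(back.predict_proba(x), want)
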