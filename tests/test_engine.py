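"""Gradient and forward checks for the autodiff engine."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from dhmfmlp.nn import engine
from dhmfmlp.nn.engine import Tensor

from conftest import gradcheck


def t64(rng, *shape):
    return Tensor(rng.normal(size=shape), requires_grad=True)


class TestForwardAgainstScipy:
    def test_conv2d_matches_scipy_correlate(self, rng):
        x = rng.normal(size=(2, 3, 7, 6))
        w = rng.normal(size=(4, 3, 3, 3))
        out = engine.conv2d(Tensor(x), Tensor(w), padding=1).data
        for b in range(2):
            for o in range(4):
                ref = sum(correlate2d(x[b, c], w[o, c], mode="same")
                          for c in range(3))
                np.testing.assert_allclose(out[b, o], ref, rtol=1e-10)

    def test_strided_conv_picks_every_other_output(self, rng):
        x = rng.normal(size=(1, 2, 8, 8))
        w = rng.normal(size=(3, 2, 3, 3))
        full = engine.conv2d(Tensor(x), Tensor(w), padding=1).data
        strided = engine.conv2d(Tensor(x), Tensor(w), padding=1, stride=2).data
        np.testing.assert_allclose(strided, full[:, :, ::2, ::2], rtol=1e-12)

    def test_upsample_bilinear_constant_preserved(self):
        x = Tensor(np.full((1, 2, 4, 4), 3.7))
        up = engine.upsample_bilinear2x(x).data
        assert up.shape == (1, 2, 8, 8)
        np.testing.assert_allclose(up, 3.7)


class TestGradients:
    def test_arithmetic_and_broadcasting(self, rng):
        a, b = t64(rng, 3, 1, 4), t64(rng, 1, 5, 4)
        gradcheck(lambda a, b: engine.tsum(engine.mul(engine.add(a, b),
                                                      engine.div(a, 2.0))), [a, b])

    def test_activations(self, rng):
        x = t64(rng, 2, 3, 4)
        for fn in (engine.relu, engine.gelu, engine.sigmoid):
            x.grad = None
            gradcheck(lambda x: engine.tsum(fn(x)), [x])

    def test_conv2d_grads(self, rng):
        x, w, b = t64(rng, 2, 4, 5, 5), t64(rng, 4, 2, 3, 3), t64(rng, 4)
        co = rng.normal(size=(2, 4, 3, 3))
        gradcheck(lambda x, w, b: engine.tsum(engine.mul(
            engine.conv2d(x, w, b, stride=2, padding=1, groups=2), co)), [x, w, b])

    def test_depthwise_conv_grads(self, rng):
        x, w = t64(rng, 1, 4, 6, 6), t64(rng, 4, 1, 3, 3)
        gradcheck(lambda x, w: engine.tsum(engine.conv2d(
            x, w, stride=2, padding=1, groups=4)), [x, w])

    def test_channel_linear_grads(self, rng):
        x, w, b = t64(rng, 2, 3, 4, 4), t64(rng, 5, 3), t64(rng, 5)
        co = rng.normal(size=(2, 5, 4, 4))
        gradcheck(lambda x, w, b: engine.tsum(engine.mul(
            engine.channel_linear(x, w, b), co)), [x, w, b])

    def test_layernorm_grads(self, rng):
        x, g, b = t64(rng, 2, 5, 3, 3), t64(rng, 5), t64(rng, 5)
        co = rng.normal(size=(2, 5, 3, 3))
        gradcheck(lambda x, g, b: engine.tsum(engine.mul(
            engine.layernorm_channel(x, g, b), co)), [x, g, b],
            rtol=1e-3, atol=1e-5)

    def test_batchnorm_train_grads(self, rng):
        x, g, b = t64(rng, 3, 2, 4, 4), t64(rng, 2), t64(rng, 2)

        co = rng.normal(size=(3, 2, 4, 4))

        def f(x, g, b):
            return engine.tsum(engine.mul(
                engine.batchnorm2d(x, g, b, np.zeros(2), np.ones(2), training=True),
                co))

        gradcheck(f, [x, g, b], rtol=1e-3, atol=1e-5)

    def test_pooling_grads(self, rng):
        x = t64(rng, 2, 3, 4, 4)
        co1 = rng.normal(size=(2, 3, 2, 2))
        gradcheck(lambda x: engine.tsum(engine.mul(
            engine.block_maxpool(x, 2, 2), co1)), [x])
        x.grad = None
        co2 = rng.normal(size=(2, 1, 4, 4))
        gradcheck(lambda x: engine.tsum(engine.mul(
            engine.max_axis(x, 1, keepdims=True), co2)), [x])

    def test_upsample_and_shift_grads(self, rng):
        x = t64(rng, 1, 2, 4, 4)
        co1 = rng.normal(size=(1, 2, 8, 8))
        gradcheck(lambda x: engine.tsum(engine.mul(
            engine.upsample_bilinear2x(x), co1)), [x])
        x.grad = None
        co2 = rng.normal(size=(1, 2, 4, 4))
        gradcheck(lambda x: engine.tsum(engine.mul(
            engine.shift2d(x, [slice(0, 1), slice(1, 2)], [-1, 2], axis=3),
            co2)), [x])

    def test_bce_with_logits_grads(self, rng):
        z = t64(rng, 2, 1, 3, 3)
        y = (rng.random((2, 1, 3, 3)) > 0.5).astype(float)
        gradcheck(lambda z: engine.bce_with_logits_mean(z, y), [z])

    def test_layout_ops_grads(self, rng):
        a, b = t64(rng, 1, 2, 2, 2), t64(rng, 1, 3, 2, 2)

        co = rng.normal(size=12)

        def f(a, b):
            cat = engine.concat([a, b], axis=1)
            tr = engine.transpose(cat, (0, 2, 1, 3))
            sl = engine.narrow(tr, 2, 1, 3)
            return engine.tsum(engine.mul(engine.reshape(sl, (-1,)), co))

        gradcheck(f, [a, b])


def test_backward_accumulates_over_reuse(rng):
    # y = x*x + x: dy/dx = 2x + 1 requires summing both paths
    x = t64(rng, 4)
    y = engine.tsum(engine.add(engine.mul(x, x), x))
    y.backward()
    np.testing.assert_allclose(x.grad, 2 * x.data + 1, rtol=1e-12)


def test_adaptive_maxpool_identity_and_blocks(rng):
    x = Tensor(rng.normal(size=(1, 2, 8, 8)))
    same = engine.adaptive_maxpool(x, (8, 8))
    assert same is x
    pooled = engine.adaptive_maxpool(x, (2, 2)).data
    blocks = x.data.reshape(1, 2, 2, 4, 2, 4)
    np.testing.assert_allclose(pooled, blocks.max(axis=(3, 5)))
    with pytest.raises(ValueError):
        engine.adaptive_maxpool(x, (3, 3))
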