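import numpy as np
import pytest

from tausynth import _nn
from tausynth._nn import Tensor
from tausynth.net import (
    DenseUNet,
    NetworkSpec,
    build_dense_unet,
    impute,
    load_model,
    parameter_count,
    save_model,
)
from tausynth.volio import Volume


class TestOps:
    """Finite-difference checks of each autograd primitive."""

    @staticmethod
    def _numeric_grad(f, x, eps=1e-3):
        g = np.zeros_like(x, dtype=np.float64)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            x[i] += eps
            fp = f(x)
            x[i] -= 2 * eps
            fm = f(x)
            x[i] += eps
            g[i] = (fp - fm) / (2 * eps)
        return g

    @pytest.mark.parametrize("op", ["relu", "maxpool", "upsample", "concat"])
    def test_backward_matches_finite_differences(self, rng, op):
        x = rng.normal(size=(2, 4, 4, 4)).astype(np.float32)

        def graph(xa):
            t = Tensor(xa)
            if op == "relu":
                out = _nn.relu(t)
            elif op == "maxpool":
                out = _nn.maxpool2(t)
            elif op == "upsample":
                out = _nn.upsample2(t)
            else:
                out = _nn.concat([t, _nn.relu(t)])
            loss = _nn.mse(out, np.zeros_like(out.data))
            return t, loss

        t, loss = graph(x)
        _nn.backward(loss)

        def f(xa):
            _, l = graph(xa.astype(np.float32))
            return float(l.data.item())

        num = self._numeric_grad(f, x.copy())
        np.testing.assert_allclose(t.grad, num, rtol=0.05, atol=1e-4)

    @staticmethod
    def _ref_conv(x, w, b=None):
        """Loop-based 'same' correlation in float64 (independent oracle)."""
        C, D, H, W = x.shape
        co, _, k = w.shape[:3]
        p = k // 2
        xp = np.pad(x.astype(np.float64), ((0, 0), (p, p), (p, p), (p, p)))
        out = np.zeros((co, D, H, W))
        for o in range(co):
            for c in range(C):
                for a in range(k):
                    for bb in range(k):
                        for cc in range(k):
                            out[o] += w[o, c, a, bb, cc] * xp[c, a : a + D, bb : bb + H, cc : cc + W]
            if b is not None:
                out[o] += b[o]
        return out

    def test_conv_forward_and_grads_match_brute_force(self, rng):
        x = rng.normal(size=(2, 4, 4, 4)).astype(np.float32)
        w = rng.normal(scale=0.5, size=(3, 2, 3, 3, 3)).astype(np.float32)
        b = rng.normal(size=3).astype(np.float32)
        t, tw, tb = Tensor(x), Tensor(w), Tensor(b)
        out = _nn.conv3d(t, tw, tb)
        ref = self._ref_conv(x, w, b)
        np.testing.assert_allclose(out.data, ref, atol=1e-5)

        loss = _nn.mse(out, np.zeros_like(out.data))
        _nn.backward(loss)
        g = 2 * ref / ref.size
        # dx: full correlation with the flipped, channel-transposed kernel
        w_t = w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        np.testing.assert_allclose(t.grad, self._ref_conv(g.astype(np.float32), w_t), atol=1e-6)
        # dW / db by direct summation
        xp = np.pad(x.astype(np.float64), ((0, 0), (1, 1), (1, 1), (1, 1)))
        dw = np.zeros_like(w, dtype=np.float64)
        for o in range(3):
            for c in range(2):
                for a in range(3):
                    for bb in range(3):
                        for cc in range(3):
                            dw[o, c, a, bb, cc] = (g[o] * xp[c, a : a + 4, bb : bb + 4, cc : cc + 4]).sum()
        np.testing.assert_allclose(tw.grad, dw, atol=1e-6)
        np.testing.assert_allclose(tb.grad, g.sum(axis=(1, 2, 3)), atol=1e-6)

    def test_maxpool_values(self):
        x = np.arange(8, dtype=np.float32).reshape(1, 2, 2, 2)
        out = _nn.maxpool2(Tensor(x))
        assert out.data.shape == (1, 1, 1, 1)
        assert out.data[0, 0, 0, 0] == 7.0

    def test_upsample_restores_pool_size(self, rng):
        x = Tensor(rng.normal(size=(3, 4, 4, 4)).astype(np.float32))
        assert _nn.upsample2(_nn.maxpool2(x)).data.shape == x.data.shape


class TestDenseUNet:
    def test_forward_shape_contract(self):
        model = build_dense_unet(NetworkSpec(depth=2, base_filters=4), seed=0)
        out = model.predict(np.zeros((1, 32, 32, 32), dtype=np.float32))
        assert out.shape == (1, 32, 32, 32)

    def test_bimodal_input_channel(self):
        model = build_dense_unet(NetworkSpec(depth=1, base_filters=2, in_channels=2), seed=0)
        out = model.predict(np.zeros((2, 16, 16, 16), dtype=np.float32))
        assert out.shape == (1, 16, 16, 16)

    def test_parameter_count_matches_hand_count(self):
        """Hand-counted weights of the concatenative graph for a tiny spec.

        depth=1, base=2, layers=2, k=3, 1 input channel:
          enc0:   conv0 1->2, conv1 (1+2)->2      (dense concat)
          bridge: conv0 2->4, conv1 (2+4)->4
          up0:    conv 4->2
          dec0:   conv0 (2+2)->2, conv1 (4+2)->2  (skip concat then dense)
          head:   conv 2->1
        """
        k3 = 27
        hand = (
            (2 * 1 * k3 + 2) + (2 * 3 * k3 + 2)      # encoder block
            + (4 * 2 * k3 + 4) + (4 * 6 * k3 + 4)    # bridge
            + (2 * 4 * k3 + 2)                        # up-convolution
            + (2 * 4 * k3 + 2) + (2 * 6 * k3 + 2)    # decoder block
            + (1 * 2 * k3 + 1)                        # linear head
        )
        spec = NetworkSpec(depth=1, base_filters=2, layers_per_block=2)
        assert parameter_count(spec) == hand
        assert build_dense_unet(spec).parameter_count == hand

    @pytest.mark.parametrize("depth,base,layers,in_ch", [(1, 2, 3, 1), (2, 4, 2, 2), (3, 2, 1, 1)])
    def test_dense_channel_arithmetic(self, depth, base, layers, in_ch):
        """Layer j of every block sees c_in + j*growth input channels."""
        from tausynth.net import _param_shapes

        spec = NetworkSpec(depth=depth, base_filters=base, layers_per_block=layers,
                           in_channels=in_ch)
        shapes = dict(_param_shapes(spec))
        for prefix, c_in, f in (
            [(f"enc{l}", in_ch if l == 0 else base * 2 ** (l - 1), base * 2**l)
             for l in range(depth)]
            + [("bridge", base * 2 ** (depth - 1), base * 2**depth)]
            + [(f"dec{l}", 2 * base * 2**l, base * 2**l) for l in range(depth)]
        ):
            for j in range(layers):
                c_out, c_seen, *_ = shapes[f"{prefix}.conv{j}"]
                assert c_out == f
                assert c_seen == c_in + j * f

    def test_zero_weights_give_zero_output(self, rng):
        model = build_dense_unet(NetworkSpec(depth=1, base_filters=2), seed=0)
        for k in model.params:
            model.params[k][:] = 0
        out = model.predict(rng.normal(size=(1, 16, 16, 16)).astype(np.float32))
        assert np.abs(out).sum() == 0

    def test_forward_deterministic_bitwise(self, rng):
        model = build_dense_unet(NetworkSpec(depth=2, base_filters=4), seed=1)
        x = rng.normal(size=(1, 16, 16, 16)).astype(np.float32)
        assert model.predict(x).tobytes() == model.predict(x).tobytes()

    def test_indivisible_input_raises(self):
        model = build_dense_unet(NetworkSpec(depth=3, base_filters=2), seed=0)
        with pytest.raises(ValueError, match="divisible by 2\\^depth"):
            model.predict(np.zeros((1, 20, 20, 20), dtype=np.float32))

    def test_impute_wraps_volumes(self, rng):
        model = build_dense_unet(NetworkSpec(depth=1, base_filters=2), seed=0)
        vol = Volume(values=rng.uniform(0, 1, size=(16, 16, 16)), space="network")
        out = impute(model, vol)
        assert out.shape == vol.shape
        assert out.space == "network"
        assert np.isfinite(out.values).all()
        with pytest.raises(ValueError, match="channel"):
            impute(model, (vol, vol))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_dense_unet(NetworkSpec(depth=1, base_filters=2), seed=4)
        x = rng.normal(size=(1, 16, 16, 16)).astype(np.float32)
        save_model(model, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        assert back.spec == model.spec
        np.testing.assert_array_equal(back.predict(x), model.predict(x))


def test_end_to_end_gradient_against_finite_difference(rng):
    """Backprop through the whole Dense-U-Net agrees with central differences.

    ReLU kinks and float32 arithmetic make individual finite differences
    noisy, so agreement is asserted on the median relative error over the
    largest-magnitude gradient entries of several layers.
    """
    model = build_dense_unet(NetworkSpec(depth=1, base_filters=2), seed=3)
    x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
    y = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
    _, grads = model.loss_and_grads(x, y)
    rel_errors = []
    for name in ["enc0.conv1.w", "bridge.conv0.w", "head.conv.w", "up0.conv.w"]:
        flat = model.params[name].reshape(-1)
        gflat = grads[name].reshape(-1)
        for idx in np.argsort(-np.abs(gflat))[:5]:
            eps = 3e-3
            old = flat[idx]
            flat[idx] = old + eps
            lp, _ = model.loss_and_grads(x, y)
            flat[idx] = old - eps
            lm, _ = model.loss_and_grads(x, y)
            flat[idx] = old
            num = (lp - lm) / (2 * eps)
            rel_errors.append(abs(float(gflat[idx]) - num) / max(abs(num), 1e-8))
    assert np.median(rel_errors) < 0.05
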