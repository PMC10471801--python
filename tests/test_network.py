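"""Attention modules against straight-line references; model contracts."""

import numpy as np
import pytest

from fieldseg.network import (ASPP, CBAM, AttMobileDeeplab, ChannelAttention,
                              NetworkConfig, SpatialAttention, StripPooling,
                              build_model, count_parameters, predict_mask)
from fieldseg.nn import Tensor


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def channel_attention_reference(x, w1, w2):
    """Pooled descriptors -> shared bottleneck -> sum -> sigmoid, written
    directly from the definition (no layer machinery)."""
    c = x.shape[0]
    avg = x.mean(axis=(1, 2))
    mx = x.max(axis=(1, 2))
    out = np.zeros(c)
    for desc in (avg, mx):
        hidden = np.maximum(w1 @ desc, 0.0)
        out += w2 @ hidden
    return _sigmoid(out)


def spatial_attention_reference(x, kernel, bias):
    """Stack channel mean/max, 7x7 convolve (padding 3), sigmoid."""
    stacked = np.stack([x.mean(axis=0), x.max(axis=0)])
    h, w = x.shape[1:]
    padded = np.pad(stacked, ((0, 0), (3, 3), (3, 3)))
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = (padded[:, i:i + 7, j:j + 7] * kernel).sum() + bias
    return _sigmoid(out)


def strip_pooling_reference(x, spl):
    """Pool -> 1-D conv -> expand -> sum -> 1x1 conv -> sigmoid -> gate."""
    def conv1x1(inp, w):
        return np.einsum("oc,chw->ohw", w[:, :, 0, 0], inp)

    def bn(inp, layer):
        mu = inp.mean(axis=(1, 2), keepdims=True)
        var = inp.var(axis=(1, 2), keepdims=True)
        xhat = (inp - mu) / np.sqrt(var + layer.eps)
        return (xhat * layer.weight.data[:, None, None]
                + layer.bias.data[:, None, None])

    r = np.maximum(bn(conv1x1(x, spl.reduce.layers[0].weight.data),
                      spl.reduce.layers[1]), 0.0)
    m, h, w = r.shape
    col = r.mean(axis=2)                      # M x H   (H x 1 strip pool)
    row = r.mean(axis=1)                      # M x W   (1 x W strip pool)
    wh = spl.conv_h.layers[0].weight.data[:, :, :, 0]   # M x M x D
    ww = spl.conv_w.layers[0].weight.data[:, :, 0, :]
    d = wh.shape[2]
    pad = d // 2
    col_p = np.pad(col, ((0, 0), (pad, pad)))
    row_p = np.pad(row, ((0, 0), (pad, pad)))
    col_c = np.zeros_like(col)
    row_c = np.zeros_like(row)
    for o in range(m):
        for t in range(col.shape[1]):
            col_c[o, t] = (col_p[:, t:t + d] * wh[o]).sum()
        for t in range(row.shape[1]):
            row_c[o, t] = (row_p[:, t:t + d] * ww[o]).sum()
    col_c = bn(col_c[:, :, None], spl.conv_h.layers[1])[:, :, 0]
    row_c = bn(row_c[:, None, :], spl.conv_w.layers[1])[:, 0, :]
    mixed = col_c[:, :, None] + row_c[:, None, :]
    gate = _sigmoid(bn(conv1x1(mixed, spl.gate.layers[0].weight.data),
                       spl.gate.layers[1]))
    return x * gate


class TestChannelAttention:
    def test_zero_weights_give_half(self):
        cam = ChannelAttention(8, reduction=4)
        cam.fc1.weight.data[:] = 0
        cam.fc2.weight.data[:] = 0
        out = cam(Tensor(np.full((1, 8, 5, 5), 3.0, dtype="f4")))
        np.testing.assert_allclose(out.data, 0.5)

    def test_shape_and_range(self, rng):
        cam = ChannelAttention(8, reduction=4, rng=rng)
        out = cam(Tensor(rng.normal(size=(1, 8, 16, 16)).astype("f4")))
        assert out.shape == (1, 8, 1, 1)
        assert ((out.data > 0) & (out.data < 1)).all()

    def test_matches_reference_on_seeded_cases(self, rng):
        for _ in range(20):
            cam = ChannelAttention(16, reduction=8, rng=rng)
            x = rng.normal(size=(16, 6, 7)).astype("f4")
            got = cam(Tensor(x[None])).data[0, :, 0, 0]
            ref = channel_attention_reference(
                x.astype(float), cam.fc1.weight.data[:, :, 0, 0],
                cam.fc2.weight.data[:, :, 0, 0])
            np.testing.assert_allclose(got, ref, rtol=1e-5, atol=1e-6)

    def test_invalid_reduction_rejected(self):
        with pytest.raises(ValueError):
            ChannelAttention(8, reduction=8)


class TestSpatialAttention:
    def test_zero_kernel_gives_half(self):
        sam = SpatialAttention()
        sam.conv.weight.data[:] = 0
        sam.conv.bias.data[:] = 0
        out = sam(Tensor(np.full((1, 8, 6, 6), 2.0, dtype="f4")))
        np.testing.assert_allclose(out.data, 0.5)

    def test_shape(self, rng):
        sam = SpatialAttention(rng=rng)
        out = sam(Tensor(rng.normal(size=(1, 8, 16, 16)).astype("f4")))
        assert out.shape == (1, 1, 16, 16)

    def test_matches_reference_on_seeded_cases(self, rng):
        for _ in range(20):
            sam = SpatialAttention(rng=rng)
            x = rng.normal(size=(5, 9, 8)).astype("f4")
            got = sam(Tensor(x[None])).data[0, 0]
            ref = spatial_attention_reference(
                x.astype(float), sam.conv.weight.data[0],
                float(sam.conv.bias.data[0]))
            np.testing.assert_allclose(got, ref, rtol=1e-5, atol=1e-6)


class TestCBAM:
    def test_zero_transform_weights_quarter_input(self, rng):
        """0.5 channel gate then 0.5 spatial gate -> 0.25 F."""
        cbam = CBAM(8, reduction=4, rng=rng)
        for p in cbam.parameters():
            p.data[:] = 0
        x = rng.normal(size=(1, 8, 6, 6)).astype("f4")
        np.testing.assert_allclose(cbam(Tensor(x)).data, 0.25 * x,
                                   rtol=1e-5, atol=1e-6)

    def test_zero_input_zero_output(self, rng):
        cbam = CBAM(8, reduction=4, rng=rng)
        out = cbam(Tensor(np.zeros((1, 8, 4, 4), dtype="f4")))
        np.testing.assert_allclose(out.data, 0.0)

    def test_shape_preserved_and_gated_below_input(self, rng):
        cbam = CBAM(16, reduction=8, rng=rng)
        x = rng.normal(size=(2, 16, 32, 32)).astype("f4")
        out = cbam(Tensor(x))
        assert out.shape == x.shape
        assert (np.abs(out.data) <= np.abs(x) + 1e-7).all()


class TestStripPooling:
    def test_zero_weights_halve_constant_input(self):
        spl = StripPooling(8, 4)
        for p in spl.parameters():
            p.data[:] = 0
        x = np.full((1, 8, 6, 6), 4.0, dtype="f4")
        np.testing.assert_allclose(spl(Tensor(x)).data, 2.0, atol=1e-6)

    def test_shape_preserved(self, rng):
        spl = StripPooling(8, 4, rng=rng)
        out = spl(Tensor(rng.normal(size=(1, 8, 16, 16)).astype("f4")))
        assert out.shape == (1, 8, 16, 16)

    def test_matches_reference_on_seeded_cases(self, rng):
        for _ in range(20):
            spl = StripPooling(6, 4, rng=rng)
            x = rng.normal(size=(6, 8, 9)).astype("f4")
            got = spl(Tensor(x[None])).data[0]
            ref = strip_pooling_reference(x.astype(float), spl)
            np.testing.assert_allclose(got, ref, rtol=1e-4, atol=1e-5)

    def test_gate_bounds_output_by_input(self, rng):
        spl = StripPooling(8, 4, rng=rng)
        x = rng.normal(size=(1, 8, 12, 12)).astype("f4")
        out = spl(Tensor(x))
        assert (np.abs(out.data) <= np.abs(x) + 1e-7).all()


class TestModel:
    def test_forward_shape_contract(self):
        net = build_model(NetworkConfig(variant="full", input_size=64))
        x = Tensor(np.random.default_rng(0).normal(
            size=(1, 3, 64, 64)).astype("f4"))
        net.eval()
        assert net(x).shape == (1, 3, 64, 64)

    def test_variants_differ_only_by_stated_modules(self):
        base = build_model(NetworkConfig(variant="baseline", input_size=64))
        att = build_model(NetworkConfig(variant="attention_only",
                                        input_size=64))
        base_names = {n for n, _ in base.named_parameters()}
        att_names = {n for n, _ in att.named_parameters()}
        assert base_names <= att_names
        assert all(n.startswith("cbam.") for n in att_names - base_names)

    def test_eval_forward_deterministic(self, rng):
        net = build_model(NetworkConfig(variant="full", input_size=64))
        net.eval()
        x = Tensor(rng.normal(size=(1, 3, 64, 64)).astype("f4"))
        a = net(x).data
        b = net(x).data
        np.testing.assert_array_equal(a, b)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible by 16"):
            NetworkConfig(input_size=100)

    def test_seeded_construction_reproducible(self):
        a = build_model(NetworkConfig(variant="full", input_size=64), seed=3)
        b = build_model(NetworkConfig(variant="full", input_size=64), seed=3)
        for (_, pa), (_, pb) in zip(a.named_parameters(),
                                    b.named_parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestPredictMask:
    def test_argmax_against_elementwise_oracle(self, rng):
        net = build_model(NetworkConfig(variant="baseline", input_size=32))
        image = rng.integers(0, 255, size=(32, 32, 3), dtype=np.uint8)
        mask = predict_mask(net, image)
        from fieldseg.network import _normalize_image

        net.eval()
        scores = net(Tensor(_normalize_image(image))).data[0]
        ref = np.zeros((32, 32), dtype=np.uint8)
        for i in range(32):
            for j in range(32):
                best, arg = -np.inf, 0
                for c in range(3):
                    if scores[c, i, j] > best:
                        best, arg = scores[c, i, j], c
                ref[i, j] = arg
        np.testing.assert_array_equal(mask, ref)
        assert set(np.unique(mask)) <= {0, 1, 2}

    def test_tie_breaks_to_lowest_class(self):
        scores = np.zeros((3, 4, 4))
        scores[1] = 1.0
        scores[2] = 1.0
        assert (scores.argmax(axis=0) == 1).all()

    def test_indivisible_image_rejected(self):
        net = build_model(NetworkConfig(variant="baseline", input_size=32))
        with pytest.raises(ValueError, match="pad"):
            predict_mask(net, np.zeros((30, 30, 3), dtype=np.uint8))


class TestParameterCounts:
    """Architecture-level counts; the printed-value checks live in the
    acceptance suite."""

    def test_count_rounding(self):
        class Dummy:
            def num_parameters(self):
                return 5_813_736

        assert count_parameters(Dummy()) == 5.814

    def test_increment_algebra(self):
        counts = {v: build_model(NetworkConfig(variant=v, input_size=64)
                                 ).num_parameters()
                  for v in ("baseline", "attention_only", "aspp_only",
                            "full")}
        cbam_a = counts["attention_only"] - counts["baseline"]
        cbam_b = counts["full"] - counts["aspp_only"]
        spl_a = counts["aspp_only"] - counts["baseline"]
        spl_b = counts["full"] - counts["attention_only"]
        assert cbam_a == cbam_b
        assert spl_a == spl_b
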