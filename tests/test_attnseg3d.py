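"""Attention modules, parameter accounting and the 3D network contract."""

import numpy as np
import pytest

from avmseg import attnseg3d as a3
from avmseg import nn
from avmseg.nn import Tensor


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@pytest.fixture()
def cam(rng):
    return a3.ChannelAttention(np.random.default_rng(0), channels=4,
                               reduction=2)


@pytest.fixture()
def sam():
    return a3.SpatialAttention(np.random.default_rng(0), kernel=3)


# ---------------------------------------------------------------------------
# Channel attention
# ---------------------------------------------------------------------------

def test_cam_zero_weights_give_half(cam):
    cam.w0.w.data[:] = 0
    cam.w1.w.data[:] = 0
    f = Tensor(np.random.default_rng(1).normal(size=(2, 4, 5, 5, 5)))
    v = cam(f).data
    assert v.shape == (2, 4, 1, 1, 1)
    assert np.allclose(v, 0.5)


def test_cam_constant_input_closed_form(cam):
    """Spatially constant channels: avg pool == max pool, so the weights
    are sigmoid(2 * MLP(c))."""
    c = np.array([0.3, -1.2, 0.7, 2.0], dtype=np.float32)
    f = Tensor(np.broadcast_to(c[None, :, None, None, None],
                               (1, 4, 6, 6, 6)).copy())
    got = cam(f).data[0, :, 0, 0, 0]
    w0, w1 = cam.w0.w.data, cam.w1.w.data
    mlp = np.maximum(c @ w0, 0) @ w1
    assert np.allclose(got, _sigmoid(2 * mlp), atol=1e-5)


def test_cam_matches_loop_oracle(cam, rng):
    f = rng.normal(size=(2, 4, 3, 3, 3)).astype(np.float32)
    got = cam(Tensor(f)).data[:, :, 0, 0, 0]
    w0, w1 = cam.w0.w.data, cam.w1.w.data
    for n in range(2):
        avg = np.array([f[n, c].mean() for c in range(4)])
        mx = np.array([f[n, c].max() for c in range(4)])
        mlp = lambda v: np.maximum(v @ w0, 0) @ w1
        exp = _sigmoid(mlp(avg) + mlp(mx))
        assert np.allclose(got[n], exp, atol=1e-5)
    assert ((got > 0) & (got < 1)).all()


def test_cam_channel_mismatch_raises(cam, rng):
    with pytest.raises(Exception):
        cam(Tensor(rng.normal(size=(1, 3, 4, 4, 4)).astype(np.float32)))


# ---------------------------------------------------------------------------
# Spatial attention
# ---------------------------------------------------------------------------

def test_sam_zero_weights_give_half(sam, rng):
    sam.conv.w.data[:] = 0
    sam.conv.b.data[:] = 0
    f = Tensor(rng.normal(size=(2, 4, 5, 5, 5)).astype(np.float32))
    v = sam(f).data
    assert v.shape == (2, 1, 5, 5, 5)
    assert np.allclose(v, 0.5)


def test_sam_constant_input_constant_interior(sam):
    f = Tensor(np.full((1, 4, 8, 8, 8), 1.3, np.float32))
    v = sam(f).data[0, 0]
    interior = v[1:-1, 1:-1, 1:-1]  # kernel 3: one-voxel boundary ring
    assert np.allclose(interior, interior.flat[0], atol=1e-6)


def test_sam_matches_loop_oracle(sam, rng):
    f = rng.normal(size=(1, 3, 4, 4, 4)).astype(np.float32)
    got = sam(Tensor(f)).data[0, 0]
    pooled = np.stack([f[0].mean(axis=0), f[0].max(axis=0)])
    w, b = sam.conv.w.data[0], float(sam.conv.b.data[0])
    pp = np.pad(pooled, ((0, 0), (1, 1), (1, 1), (1, 1)))
    exp = np.zeros((4, 4, 4))
    for i in range(4):
        for j in range(4):
            for k in range(4):
                acc = b
                for c in range(2):
                    for di in range(3):
                        for dj in range(3):
                            for dk in range(3):
                                acc += w[c, di, dj, dk] * \
                                    pp[c, i + di, j + dj, k + dk]
                exp[i, j, k] = _sigmoid(acc)
    assert np.allclose(got, exp, atol=1e-4)
    assert ((got > 0) & (got < 1)).all()


# ---------------------------------------------------------------------------
# Attentional block
# ---------------------------------------------------------------------------

def _unit_attention_block(c):
    cfg = a3.NetworkConfig(in_channels=c, base_width=c, levels=2,
                           mlp_reduction=1, sam_kernel=3)
    blk = a3.AttentionalBlock(np.random.default_rng(0), c, c, cfg)
    return blk


def test_attention_substep_identity_with_unit_weights(rng):
    blk = _unit_attention_block(4)
    f = Tensor(rng.normal(size=(1, 4, 4, 4, 4)).astype(np.float32))
    vc = blk.cam(f)
    vs = blk.sam(f * vc)
    # force both weight maps to exactly one
    vc.data[:] = 1.0
    vs.data[:] = 1.0
    out = (f * vc) * vs
    assert np.array_equal(out.data, f.data)


def test_attention_contracts_magnitudes(rng):
    blk = _unit_attention_block(4)
    f = Tensor(rng.normal(size=(1, 4, 4, 4, 4)).astype(np.float32))
    f1 = f * blk.cam(f)
    out = f1 * blk.sam(f1)
    assert (np.abs(out.data) <= np.abs(f.data) + 1e-7).all()


def test_ablated_block_is_conv_path_only(rng):
    cfg = a3.NetworkConfig(in_channels=4, base_width=4, levels=2,
                           mlp_reduction=1, use_attention=False)
    blk = a3.AttentionalBlock(np.random.default_rng(0), 4, 4, cfg)
    assert not hasattr(blk, "cam") and not hasattr(blk, "sam")
    f = Tensor(rng.normal(size=(1, 4, 4, 4, 4)).astype(np.float32))
    manual = blk.norm2(blk.conv2(blk.norm1(blk.conv1(f)).relu())).relu()
    assert np.array_equal(blk(f).data, manual.data)


# ---------------------------------------------------------------------------
# Parameter accounting
# ---------------------------------------------------------------------------

def test_depthwise_separable_param_formula():
    std, sep = a3.depthwise_separable_params(3, 16, 32, with_bias=False)
    assert (std, sep) == (13824, 944)
    std1, sep1 = a3.depthwise_separable_params(1, 1, 1, with_bias=False)
    assert (std1, sep1) == (1, 2)  # no reduction at k=1
    # reduction holds whenever c_out > 1 and k > 1
    for k, ci, co in [(3, 2, 2), (3, 8, 4), (5, 4, 16), (7, 2, 2)]:
        std, sep = a3.depthwise_separable_params(k, ci, co)
        assert sep < std


def test_built_layer_matches_predicted_count():
    rng = np.random.default_rng(0)
    layer = nn.DepthwiseSeparableConv(rng, 16, 32, 3, 3, bias=False)
    _, sep = a3.depthwise_separable_params(3, 16, 32, with_bias=False)
    assert sum(p.data.size for p in layer.parameters()) == sep
    layer_b = nn.DepthwiseSeparableConv(rng, 16, 32, 3, 3, bias=True)
    _, sep_b = a3.depthwise_separable_params(3, 16, 32, with_bias=True)
    assert sum(p.data.size for p in layer_b.parameters()) == sep_b
    std_layer = nn.Conv(rng, 16, 32, 3, 3, bias=False)
    std, _ = a3.depthwise_separable_params(3, 16, 32, with_bias=False)
    assert std_layer.w.data.size == std


def test_depthwise_model_smaller_than_standard_twin():
    kw = dict(in_channels=4, base_width=8, levels=3)
    small = a3.build_network(a3.NetworkConfig(**kw, use_depthwise=True))
    big = a3.build_network(a3.NetworkConfig(**kw, use_depthwise=False))
    assert small.n_parameters() < big.n_parameters()


def test_model_total_equals_sum_of_module_counts():
    net = a3.build_network(a3.NetworkConfig(in_channels=2, base_width=4,
                                            levels=3, mlp_reduction=4))
    total = sum(p.data.size for p in net.parameters())
    assert net.n_parameters() == total
    named = net.named_parameters()
    assert sum(v.data.size for v in named.values()) == total


# ---------------------------------------------------------------------------
# Network contract
# ---------------------------------------------------------------------------

def test_network_output_shape_and_range(rng):
    net = a3.build_network(a3.NetworkConfig(in_channels=2, base_width=4,
                                            levels=3, mlp_reduction=4), roi_size=16)
    x = rng.normal(size=(1, 2, 16, 16, 16)).astype(np.float32)
    y = net(Tensor(x))
    assert y.shape == (1, 2, 16, 16, 16)
    assert (np.abs(y.data) < 1.0).all()  # tanh range


def test_bottleneck_resolution_halves_per_level():
    cfg = a3.NetworkConfig(in_channels=1, base_width=2, levels=5,
                           mlp_reduction=2)
    net = a3.build_network(cfg, roi_size=128)
    shapes = []
    orig = nn.maxpool2_nd

    def spy(x, nd):
        out = orig(x, nd)
        shapes.append(out.shape[2:])
        return out
    nn_mod_pool = a3.nn.maxpool2_nd
    a3.nn.maxpool2_nd = spy
    try:
        net(Tensor(np.zeros((1, 1, 128, 128, 128), np.float32)))
    finally:
        a3.nn.maxpool2_nd = nn_mod_pool
    assert shapes[:4] == [(64, 64, 64), (32, 32, 32), (16, 16, 16), (8, 8, 8)]


def test_indivisible_roi_rejected():
    with pytest.raises(ValueError):
        a3.build_network(a3.NetworkConfig(in_channels=1, base_width=2, levels=5,
                                          mlp_reduction=2), roi_size=24)


def test_finite_gradients_everywhere(rng):
    net = a3.build_network(a3.NetworkConfig(in_channels=2, base_width=4,
                                            levels=2, mlp_reduction=4))
    x = rng.normal(size=(1, 2, 8, 8, 8)).astype(np.float32)
    y = net(Tensor(x))
    (y * y).sum().backward()
    for name, p in net.named_parameters().items():
        assert p.grad is not None, name
        assert np.isfinite(p.grad).all(), name


def test_ablated_network_trains(rng):
    net = a3.build_network(a3.NetworkConfig(in_channels=2, base_width=4, levels=2,
                                            mlp_reduction=4, use_attention=False))
    x = rng.normal(size=(1, 2, 8, 8, 8)).astype(np.float32)
    y = net(Tensor(x))
    (y * y).sum().backward()
    assert all(p.grad is not None for p in net.parameters())


def test_predict_mask_tie_and_forced_cases(default_case):
    class TwoChannel:
        def __init__(self, val0, val1):
            self.v0, self.v1 = val0, val1
            from avmseg.attnseg3d import NetworkConfig
            self.cfg = NetworkConfig(in_channels=4, base_width=8)

        def __call__(self, x):
            n = x.shape[0]
            sp = x.shape[2:]
            out = np.empty((n, 2) + sp, np.float32)
            out[:, 0] = self.v0
            out[:, 1] = self.v1
            return Tensor(out)

    x = np.zeros((4, 8, 8, 8), np.float32)
    tie = a3.predict_mask(TwoChannel(0.3, 0.3), x)
    assert tie.is_empty()  # ties break to background
    fg = a3.predict_mask(TwoChannel(-0.1, 0.2), x)
    assert fg.count() == 8 ** 3


def test_model_checkpoint_round_trip(tmp_path, rng):
    cfg = a3.NetworkConfig(in_channels=2, base_width=4, levels=2,
                           mlp_reduction=4, seed=8)
    net = a3.build_network(cfg)
    p = tmp_path / "seg.npz"
    a3.save_model(p, net)
    net2 = a3.load_model(p)
    assert net2.cfg == cfg
    x = rng.normal(size=(1, 2, 8, 8, 8)).astype(np.float32)
    assert np.array_equal(net(Tensor(x)).data, net2(Tensor(x)).data)
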