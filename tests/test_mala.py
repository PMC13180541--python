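"""Magnitude-aware linear attention: kernel map, core, gate, full block."""

import numpy as np
import pytest

from lesiondetr import nn
from lesiondetr.nn.tensor import Tensor
from lesiondetr.mala import (
    AIFIMALABlock,
    dw_lpe,
    kernel_map,
    mala_core,
    mala_fuse,
    qkvo_project,
)
from lesiondetr.rope_decay import build_axial_frequencies, rope2d_rotate


class TestKernelMap:
    def test_closed_form_values(self):
        assert kernel_map(np.array(0.0)) == pytest.approx(1.0)
        assert kernel_map(np.array(3.0)) == pytest.approx(4.0)
        assert kernel_map(np.array(-1.0)) == pytest.approx(np.exp(-1.0))

    def test_strictly_positive_everywhere(self, rng):
        x = rng.standard_normal(1000) * 10
        assert np.all(kernel_map(x) > 0)


class TestQKVOProjection:
    def test_identity_q_slice_passes_input_through(self, rng):
        C = 4
        conv = nn.Conv2d(C, 4 * C, 1)
        w = np.zeros_like(conv.weight.data)
        w[:C, :, 0, 0] = np.eye(C)
        conv.weight.data = w
        conv.bias.data = np.zeros_like(conv.bias.data)
        x = Tensor(rng.standard_normal((1, C, 3, 3)))
        q, k, v, o = qkvo_project(x, conv)
        np.testing.assert_allclose(q.data, x.data, atol=1e-12)
        for t in (k, v, o):
            assert np.all(t.data == 0)

    def test_fused_equals_four_separate_linear_maps(self, rng):
        C = 6
        conv = nn.Conv2d(C, 4 * C, 1)
        conv.weight.data = rng.standard_normal(conv.weight.shape)
        conv.bias.data = rng.standard_normal(conv.bias.shape)
        x = rng.standard_normal((2, C, 4, 5))
        outs = qkvo_project(Tensor(x), conv)
        W = conv.weight.data[:, :, 0, 0]
        flat = x.transpose(0, 2, 3, 1).reshape(-1, C)
        for i, t in enumerate(outs):
            expect = (
                (flat @ W[i * C : (i + 1) * C].T + conv.bias.data[i * C : (i + 1) * C])
                .reshape(2, 4, 5, C)
                .transpose(0, 3, 1, 2)
            )
            np.testing.assert_allclose(t.data, expect, atol=1e-6)

    def test_channel_mismatch_raises(self, rng):
        conv = nn.Conv2d(4, 16, 1)
        with pytest.raises(ValueError):
            qkvo_project(Tensor(rng.standard_normal((1, 8, 3, 3))), conv)


def _loop_mala_core(q, k, v, rope, eps):
    """Independent per-position reference of the magnitude-corrected core."""
    C, H, W = q.shape[1:]
    qr = rope2d_rotate(q.reshape(1, 1, C, H, W), rope).reshape(C, H * W).T
    kr = rope2d_rotate(k.reshape(1, 1, C, H, W), rope).reshape(C, H * W).T
    vt = v.reshape(1, C, H * W)[0].T
    pq, pk = kernel_map(qr), kernel_map(kr)
    kmean = pk.mean(axis=0)
    vmean = vt.mean(axis=0)
    N = H * W
    out = np.zeros((N, C))
    for n in range(N):
        z = sum(pq[n, e] * kmean[e] for e in range(C))
        for d in range(C):
            linear = 0.0
            for m in range(N):
                for e in range(C):
                    linear += pq[n, e] * pk[m, e] * vt[m, d]
            out[n, d] = linear * (1 + 1 / (z + eps)) - z * vmean[d]
    return out.T.reshape(1, C, H, W)


class TestMalaCore:
    def test_zero_values_give_zero_output(self, rng):
        rope = build_axial_frequencies(4)
        q = Tensor(rng.standard_normal((1, 4, 2, 3)))
        k = Tensor(rng.standard_normal((1, 4, 2, 3)))
        v = Tensor(np.zeros((1, 4, 2, 3)))
        out = mala_core(q, k, v, rope, num_heads=1)
        np.testing.assert_allclose(out.data, 0, atol=1e-12)

    def test_single_position_recovers_value_vector(self, rng):
        """At N=1 the closed form is out = (z/(z+eps)) * V."""
        rope = build_axial_frequencies(8)
        eps = 1e-6
        for _ in range(10):
            q = rng.standard_normal((1, 8, 1, 1))
            k = rng.standard_normal((1, 8, 1, 1)) + 1.0
            v = rng.standard_normal((1, 8, 1, 1))
            out = mala_core(Tensor(q), Tensor(k), Tensor(v), rope, 1, eps).data
            pq = kernel_map(q[0, :, 0, 0])
            pk = kernel_map(k[0, :, 0, 0])
            z = float(pq @ pk)
            np.testing.assert_allclose(out, z / (z + eps) * v, rtol=1e-9)
            if np.linalg.norm(pq) * np.linalg.norm(pk) >= 1.0:
                rel = np.linalg.norm(out - v) / np.linalg.norm(v)
                assert rel <= 10 * eps

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_vectorized_matches_triple_loop_reference(self, seed):
        rng = np.random.default_rng(seed)
        rope = build_axial_frequencies(4)
        q = rng.standard_normal((1, 4, 3, 4))
        k = rng.standard_normal((1, 4, 3, 4))
        v = rng.standard_normal((1, 4, 3, 4))
        fast = mala_core(Tensor(q), Tensor(k), Tensor(v), rope, 1).data
        slow = _loop_mala_core(q, k, v, rope, 1e-6)
        np.testing.assert_allclose(fast, slow, atol=1e-5)

    def test_query_scaling_changes_output_unlike_normalized_linear_attention(self, rng):
        """The homogeneous normalized-kernel oracle is scale-invariant; the
        magnitude-corrected core is not."""

        def normalized_relu_attention(q, k, v):
            pq = np.maximum(q, 0)
            pk = np.maximum(k, 0)
            w = pq @ pk.T
            return (w / w.sum(axis=1, keepdims=True)) @ v

        # positive q/k keep the kernel away from the undefined all-zero row;
        # ReLU is then exactly homogeneous and doubling is an exact scaling
        q = np.abs(rng.standard_normal((6, 4)))
        k = np.abs(rng.standard_normal((6, 4)))
        v = rng.standard_normal((6, 4))
        base = normalized_relu_attention(q, k, v)
        scaled = normalized_relu_attention(2 * q, k, v)
        np.testing.assert_array_equal(base, scaled)  # exactly invariant

        rope = build_axial_frequencies(4)
        qs = [Tensor(q.T.reshape(1, 4, 2, 3)), Tensor(2 * q.T.reshape(1, 4, 2, 3))]
        kk = Tensor(k.T.reshape(1, 4, 2, 3))
        vv = Tensor(v.T.reshape(1, 4, 2, 3))
        o1 = mala_core(qs[0], kk, vv, rope, 1).data
        o2 = mala_core(qs[1], kk, vv, rope, 1).data
        rel = np.linalg.norm(o1 - o2) / np.linalg.norm(o1)
        assert rel > 1e-3

    def test_non_finite_input_reported_with_location(self, rng):
        rope = build_axial_frequencies(4)
        q = rng.standard_normal((1, 4, 2, 2))
        q[0, 1, 0, 1] = np.nan
        with pytest.raises(FloatingPointError, match="q"):
            mala_core(Tensor(q), Tensor(np.zeros_like(q)), Tensor(np.zeros_like(q)), rope, 1)

    @pytest.mark.parametrize("side", [4, 16, 64])
    def test_memory_grows_linearly_not_quadratically(self, side, rng):
        """Peak dense intermediates scale as N*d and d*d, never N*N."""
        rope = build_axial_frequencies(4)
        q = Tensor(rng.standard_normal((1, 4, side, side)).astype(np.float32))
        sizes = []
        orig = nn.matmul

        def spy(a, b):
            out = orig(a, b)
            sizes.append(out.size)
            return out

        nn.tensor_matmul = None
        import lesiondetr.mala as mala_mod

        mala_mod.nn.matmul, saved = spy, orig
        try:
            mala_core(q, q, q, rope, 1)
        finally:
            mala_mod.nn.matmul = saved
        N = side * side
        assert max(sizes) <= max(N * 4, 16)
        assert all(s < N * N for s in sizes)


class TestLocalEnhancement:
    def test_zero_input_and_delta_kernel(self, rng):
        conv = nn.Conv2d(3, 3, 5, padding=2, groups=3, bias=False)
        assert np.all(dw_lpe(Tensor(np.zeros((1, 3, 6, 6))), conv).data == 0)
        w = np.zeros_like(conv.weight.data)
        w[:, 0, 2, 2] = 1.0  # centered delta
        conv.weight.data = w
        v = Tensor(rng.standard_normal((2, 3, 6, 6)))
        np.testing.assert_allclose(dw_lpe(v, conv).data, v.data, atol=1e-7)

    def test_no_cross_channel_leakage(self, rng):
        conv = nn.Conv2d(4, 4, 5, padding=2, groups=4, bias=False)
        v = rng.standard_normal((1, 4, 8, 8))
        base = dw_lpe(Tensor(v), conv).data
        v2 = v.copy()
        v2[0, 3] += rng.standard_normal((8, 8))
        pert = dw_lpe(Tensor(v2), conv).data
        np.testing.assert_array_equal(base[0, :3], pert[0, :3])
        assert not np.allclose(base[0, 3], pert[0, 3])

    def test_dense_conv_rejected(self):
        with pytest.raises(ValueError):
            dw_lpe(Tensor(np.zeros((1, 3, 4, 4))), nn.Conv2d(3, 3, 5, padding=2))


class TestGateFusion:
    def _identity_proj(self, C):
        proj = nn.Conv2d(C, C, 1)
        w = np.zeros_like(proj.weight.data)
        w[:, :, 0, 0] = np.eye(C)
        proj.weight.data = w
        proj.bias.data = np.zeros_like(proj.bias.data)
        return proj

    def test_closed_gate_yields_zero(self, rng):
        C = 4
        core = Tensor(rng.standard_normal((1, C, 3, 3)))
        lpe = Tensor(rng.standard_normal((1, C, 3, 3)))
        out = mala_fuse(core, lpe, Tensor(np.zeros((1, C, 3, 3))), self._identity_proj(C))
        assert np.all(out.data == 0)

    def test_open_gate_identity_projection_passes_sum(self, rng):
        C = 4
        core = Tensor(rng.standard_normal((1, C, 3, 3)))
        lpe = Tensor(rng.standard_normal((1, C, 3, 3)))
        out = mala_fuse(core, lpe, Tensor(np.ones((1, C, 3, 3))), self._identity_proj(C))
        np.testing.assert_allclose(out.data, core.data + lpe.data, atol=1e-7)

    def test_additive_in_core_plus_lpe_at_fixed_gate(self, rng):
        C = 4
        proj = nn.Conv2d(C, C, 1)
        proj.bias.data = np.zeros_like(proj.bias.data)
        o = Tensor(rng.standard_normal((1, C, 3, 3)))
        a = Tensor(rng.standard_normal((1, C, 3, 3)))
        b = Tensor(rng.standard_normal((1, C, 3, 3)))
        zero = Tensor(np.zeros((1, C, 3, 3)))
        lhs = mala_fuse(a, b, o, proj).data
        rhs = mala_fuse(a, zero, o, proj).data + mala_fuse(zero, b, o, proj).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-6)


class TestFullBlock:
    def test_shape_preserving(self, rng):
        nn.manual_seed(0)
        block = AIFIMALABlock(32, 4)
        x = Tensor(rng.standard_normal((2, 32, 5, 5)).astype(np.float32))
        assert block(x).shape == (2, 32, 5, 5)

    def test_zeroed_projections_reduce_to_layernorm_of_input(self, rng):
        """With every projection weight/bias zero, Y = 0 and the update is
        LN(X + LN(0)) = LN(X)."""
        nn.manual_seed(0)
        block = AIFIMALABlock(8, 2)
        for p in [block.qkvo, block.lpe, block.proj, block.ffn1, block.ffn2]:
            p.weight.data = np.zeros_like(p.weight.data)
            if p.bias is not None:
                p.bias.data = np.zeros_like(p.bias.data)
        x = Tensor(rng.standard_normal((1, 8, 3, 3)))
        out = block(x).data
        mu = x.data.mean(axis=1, keepdims=True)
        xc = x.data - mu
        expect = xc / np.sqrt((xc**2).mean(axis=1, keepdims=True) + 1e-5)
        np.testing.assert_allclose(out, expect, atol=1e-6)

    def test_batch_independence(self, rng):
        nn.manual_seed(3)
        block = AIFIMALABlock(16, 4)
        x = rng.standard_normal((1, 16, 4, 4)).astype(np.float32)
        doubled = block(Tensor(np.concatenate([x, x], axis=0))).data
        np.testing.assert_allclose(doubled[0], doubled[1], atol=1e-6)
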