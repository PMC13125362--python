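"""Network: convolution oracles, parameter accounting, attention and gating
algebra, shape contracts and the finite-difference gradient check."""

import math

import numpy as np
import pytest

from pdscribe import network as nw


def brute_force_conv(x, w):
    """Direct quadruple-loop 'same' convolution oracle (H, W, M) x (K,K,M,N)."""
    k, _, m, n = w.shape
    h, wd, _ = x.shape
    p = k // 2
    xp = np.pad(x, ((p, k - 1 - p), (p, k - 1 - p), (0, 0)))
    out = np.zeros((h, wd, n))
    for i in range(h):
        for j in range(wd):
            for nn in range(n):
                acc = 0.0
                for u in range(k):
                    for v in range(k):
                        for mm in range(m):
                            acc += w[u, v, mm, nn] * xp[i + u, j + v, mm]
                out[i, j, nn] = acc
    return out


class TestConvolutions:
    def test_identity_pointwise_kernel(self, rng):
        x = rng.random((6, 6, 3))
        w = np.eye(3)[None, None]  # 1x1x3x3 identity channel mix
        assert np.allclose(nw.conv_standard(x, w), x)

    def test_centred_delta_kernel_is_identity(self):
        x = np.arange(25, dtype=float).reshape(5, 5, 1)
        w = np.zeros((3, 3, 1, 1))
        w[1, 1, 0, 0] = 1.0
        assert np.allclose(nw.conv_standard(x, w), x)

    def test_standard_conv_matches_brute_force(self, rng):
        x = rng.random((5, 5, 2))
        w = rng.normal(size=(3, 3, 2, 4))
        assert np.allclose(nw.conv_standard(x, w), brute_force_conv(x, w),
                           atol=1e-10)

    def test_separable_delta_identity(self, rng):
        x = rng.random((6, 6, 3))
        dw = np.zeros((3, 3, 3))
        dw[1, 1, :] = 1.0
        pw = np.eye(3)
        assert np.allclose(nw.depthwise_separable(x, dw, pw), x)

    def test_separable_equals_standard_for_factorizable_kernel(self, rng):
        """When K[u,v,m,n] = K_dw[u,v,m] * K_pw[m,n], both paths agree."""
        x = rng.random((5, 5, 2))
        dw = rng.normal(size=(3, 3, 2))
        pw = rng.normal(size=(2, 4))
        full = np.einsum("uvm,mn->uvmn", dw, pw)
        a = nw.depthwise_separable(x, dw, pw)
        b = nw.conv_standard(x, full)
        assert np.max(np.abs(a - b)) < 1e-6

    def test_parameter_counts(self):
        assert nw.params_standard_conv(3, 2, 4) == 72      # K^2 M N
        assert nw.params_separable_conv(3, 2, 4) == 26     # K^2 M + M N

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            nw.conv_standard(rng.random((5, 5, 3)), rng.normal(size=(3, 3, 2, 4)))
        with pytest.raises(ValueError):
            nw.depthwise_separable(rng.random((5, 5, 3)),
                                   rng.normal(size=(3, 3, 2)),
                                   rng.normal(size=(2, 4)))


class TestCcr:
    def test_degenerate_value(self):
        assert nw.ccr(1, 1) == 2.0

    def test_matches_operation_count_ratio(self):
        """1/N + 1/K^2 equals the multiply-accumulate ratio of the two
        implementations counted directly."""
        k, m, n, h, w = 3, 2, 64, 8, 8
        macs_standard = h * w * k * k * m * n
        macs_separable = h * w * (k * k * m + m * n)
        assert nw.ccr(k, n) == pytest.approx(macs_separable / macs_standard)
        assert nw.ccr(3, 64) == pytest.approx(0.126736, abs=1e-6)

    def test_strictly_decreasing_in_n(self):
        vals = [nw.ccr(3, n) for n in (1, 2, 8, 64, 512)]
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestAttention:
    def _params(self, d, heads, rng, zero_qk=False, identity_out=False):
        wq = np.zeros((d, d)) if zero_qk else rng.normal(size=(d, d))
        wk = np.zeros((d, d)) if zero_qk else rng.normal(size=(d, d))
        wv = rng.normal(size=(d, d))
        wo = np.eye(d) if identity_out else rng.normal(size=(d, d))
        return nw.AttentionParams(heads, wq, wk, wv, wo)

    def test_zero_query_key_gives_uniform_attention(self, rng):
        """With zero Q/K the softmax is uniform, so each pre-residual output
        token is the mean of the value-projected tokens."""
        d, L = 8, 5
        p = self._params(d, 2, rng, zero_qk=True, identity_out=True)
        tokens = rng.random((L, d))
        out = nw.multi_head_attention(tokens, p)
        expected = tokens + np.mean(tokens @ p.wv, axis=0, keepdims=True)
        assert np.allclose(out, expected)

    def test_permutation_equivariance(self, rng):
        d, L = 8, 6
        p = self._params(d, 4, rng)
        tokens = rng.random((L, d))
        perm = rng.permutation(L)
        assert np.allclose(nw.multi_head_attention(tokens, p)[perm],
                           nw.multi_head_attention(tokens[perm], p))

    def test_single_head_matches_explicit_loops(self, rng):
        """H=1, L=3, d=4 against softmax(QK^T/sqrt(d)) V by hand."""
        d, L = 4, 3
        p = self._params(d, 1, rng)
        x = rng.random((L, d))
        q, k, v = x @ p.wq, x @ p.wk, x @ p.wv
        out_ref = np.zeros((L, d))
        for i in range(L):
            scores = np.array([q[i] @ k[j] / math.sqrt(d) for j in range(L)])
            a = np.exp(scores - scores.max())
            a /= a.sum()
            out_ref[i] = sum(a[j] * v[j] for j in range(L))
        out_ref = x + out_ref @ p.wo
        assert np.allclose(nw.multi_head_attention(x, p), out_ref, atol=1e-10)

    def test_head_divisibility_enforced(self, rng):
        with pytest.raises(ValueError):
            self._params(6, 4, rng)


class TestGating:
    def _gate(self, d=8, hidden=4, rng=None):
        rng = rng or np.random.default_rng(1)
        return nw.GateParams(rng.normal(size=(hidden, d)), rng.normal(size=hidden),
                             rng.normal(size=hidden))

    def test_identical_branches_share_weight_equally(self, rng):
        z = rng.random((7, 7, 8))
        alphas = nw.gate_weights([z, z, z], self._gate())
        assert np.allclose(alphas, [1 / 3] * 3)

    def test_softmax_conservation(self, rng):
        for _ in range(10):
            zs = [rng.normal(size=(7, 7, 8)) * 10 for _ in range(3)]
            alphas = nw.gate_weights(zs, self._gate(rng=rng))
            assert abs(alphas.sum() - 1.0) < 1e-12
            assert np.all(alphas > 0)

    def test_hand_computed_scores(self):
        """Scores (1, 0, 0) -> alpha = (e, 1, 1) / (e + 2)."""
        e = math.e
        expected = np.array([e, 1, 1]) / (e + 2)
        assert np.allclose(nw.softmax(np.array([1.0, 0.0, 0.0])), expected)


class TestFuseAndClassify:
    def test_concatenated_depth_and_output_length(self, rng):
        d, dp = 16, 8
        zs = [rng.random((7, 7, d)) for _ in range(3)]
        head = nw.HeadParams(rng.normal(size=(3 * d, dp)), np.zeros(dp),
                             rng.normal(size=(2, dp)), np.zeros(2))
        vec = nw.fuse_reduce_pool(zs, np.array([0.5, 0.3, 0.2]), head)
        assert vec.shape == (dp,)

    def test_degenerate_alpha_zeroes_other_branches(self, rng):
        d = 4
        zs = [np.full((7, 7, d), 2.0) for _ in range(3)]
        head = nw.HeadParams(np.eye(3 * d), np.zeros(3 * d),
                             rng.normal(size=(2, 3 * d)), np.zeros(2))
        vec = nw.fuse_reduce_pool(zs, np.array([1.0, 0.0, 0.0]), head)
        assert np.allclose(vec[d:], 0.0)
        assert np.allclose(vec[:d], 2.0)

    def test_classify_zero_head_is_uniform(self):
        head = nw.HeadParams(np.eye(4), np.zeros(4), np.zeros((2, 4)), np.zeros(2))
        assert np.allclose(nw.classify(np.ones(4), head), [0.5, 0.5])

    def test_classify_manual_softmax(self):
        head = nw.HeadParams(np.eye(2), np.zeros(2),
                             np.array([[2.0, 0.0], [0.0, 0.0]]), np.zeros(2))
        probs = nw.classify(np.array([1.0, 0.0]), head)
        e2 = math.exp(2)
        assert np.allclose(probs, [e2 / (e2 + 1), 1 / (e2 + 1)])
        assert probs == pytest.approx([0.8808, 0.1192], abs=1e-4)

    def test_posteriors_sum_to_one(self, rng):
        head = nw.HeadParams(np.eye(4), np.zeros(4),
                             rng.normal(size=(2, 4)) * 50, rng.normal(size=2))
        for _ in range(20):
            p = nw.classify(rng.normal(size=4) * 10, head)
            assert abs(p.sum() - 1.0) < 1e-12


class TestModel:
    def test_full_shape_pipeline(self, rng):
        """256x256x3 -> stage dims (64,128,256,512,512) at spatial sizes
        (128,64,32,16,8); branches 7x7x192; fused vector 32; posterior 2."""
        model = nw.MgmaDscnn(nw.ModelConfig(), seed=0)
        x = rng.random((256, 256, 3))
        stage_maps, _ = model.backbone(x[None])
        dims = [(m.shape[1], m.shape[3]) for m in stage_maps]
        assert dims == [(128, 64), (64, 128), (32, 256), (16, 512), (8, 512)]
        f1, f2, f3 = nw.backbone_forward(x, model)
        assert f1.shape == (32, 32, 256)
        assert f2.shape == (16, 16, 512)
        assert f3.shape == (8, 8, 512)
        probs = model.forward(x)
        assert probs.shape == (2,)
        assert abs(probs.sum() - 1.0) < 1e-12

    def test_branch_projection_shape_and_error(self, rng):
        model = nw.MgmaDscnn(nw.ModelConfig.reduced(64), seed=0)
        f = rng.random((8, 8, 64))
        z = nw.project_branch(f, model.params["br3_pw"], model.params["br3_b"])
        assert z.shape == (7, 7, 192)
        with pytest.raises(ValueError):
            nw.project_branch(rng.random((6, 6, 64)), model.params["br3_pw"],
                              model.params["br3_b"])

    def test_adaptive_pool_window_means(self):
        """8x8 -> 7x7: each output cell is the mean of its source window
        ([floor(i*8/7), ceil((i+1)*8/7)) bounds), checked by hand."""
        x = np.arange(64, dtype=float).reshape(1, 8, 8, 1)
        out = nw._adaptive_avgpool_fwd(x, 7)
        grid = x[0, :, :, 0]
        for i in range(7):
            r0, r1 = (i * 8) // 7, -((-(i + 1) * 8) // 7)
            for j in range(7):
                c0, c1 = (j * 8) // 7, -((-(j + 1) * 8) // 7)
                assert out[0, i, j, 0] == pytest.approx(grid[r0:r1, c0:c1].mean())

    @staticmethod
    def _tiny32():
        return nw.ModelConfig(
            input_hw=32,
            backbone=nw.BackboneConfig(filters=(8, 8, 16, 16, 16),
                                       pool_strides=(2, 2, 1, 1, 1)),
            branches=nw.BranchConfig(proj_hw=7, depth=16), attn_heads=2,
            gate_hidden=8, reduced_dim=8)

    def test_inference_deterministic(self, rng):
        model = nw.MgmaDscnn(self._tiny32(), seed=3)
        x = rng.random((2, 32, 32, 3))
        assert np.array_equal(model.forward(x), model.forward(x))

    def test_count_parameters_matches_enumeration(self):
        for cfg in (nw.ModelConfig(), nw.ModelConfig.reduced(64)):
            model = nw.MgmaDscnn(cfg, seed=0)
            total, groups = nw.count_parameters(cfg, breakdown=True)
            assert total == model.num_params()
            assert sum(groups.values()) == total

    def test_head_only_parameter_count(self):
        cfg = nw.ModelConfig()
        _, groups = nw.count_parameters(cfg, breakdown=True)
        assert groups["head"] == 2 * 32 + 2  # C*D' + C = 66

    def test_separable_backbone_smaller_than_standard(self):
        cfg = nw.ModelConfig()
        k = cfg.backbone.kernel_size
        cin = cfg.input_channels
        sep_total = std_total = 0
        for f in cfg.backbone.filters:
            for _ in range(2):
                sep_total += nw.params_separable_conv(k, cin, f, bias=True)
                std_total += nw.params_standard_conv(k, cin, f, bias=True)
                cin = f
        assert sep_total < std_total

    def test_input_shape_validated(self, rng):
        model = nw.MgmaDscnn(nw.ModelConfig.reduced(64), seed=0)
        with pytest.raises(ValueError):
            model.forward(rng.random((32, 32, 3)))

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = nw.MgmaDscnn(self._tiny32(), seed=5)
        x = rng.random((1, 32, 32, 3))
        p0 = model.forward(x)
        path = tmp_path / "model.ckpt"
        nw.save_checkpoint(model, path)
        loaded = nw.load_checkpoint(path)
        assert np.allclose(loaded.forward(x), p0)


def test_gradients_match_finite_differences():
    """Central-difference check of the training-mode loss gradient on a
    sampled subset of parameters of a tiny model (eps = 1e-7)."""
    cfg = nw.ModelConfig(
        input_hw=16,
        backbone=nw.BackboneConfig(filters=(4, 4, 8, 8, 8),
                                   pool_strides=(2, 1, 1, 1, 1)),
        branches=nw.BranchConfig(proj_hw=7, depth=8), attn_heads=2,
        gate_hidden=4, reduced_dim=4, dropout=0.0)
    model = nw.MgmaDscnn(cfg, seed=1)
    x = np.random.default_rng(2).random((2, 16, 16, 3))
    y = np.array([1, 0])

    def loss():
        val, _ = model.loss_and_grad(x, y, train=True, rng=None)
        return val

    _, grads = model.loss_and_grad(x, y, train=True, rng=None)
    rng = np.random.default_rng(4)
    checked = 0
    for name, arr in model.params.items():
        flat = arr.reshape(-1)
        n_check = max(1, flat.size // 100)
        for i in rng.choice(flat.size, size=min(n_check, 4), replace=False):
            eps = 1e-7
            old = flat[i]
            flat[i] = old + eps
            lp = loss()
            flat[i] = old - eps
            lm = loss()
            flat[i] = old
            fd = (lp - lm) / (2 * eps)
            an = grads[name].reshape(-1)[i]
            rel = abs(fd - an) / max(abs(fd) + abs(an), 1e-4)
            assert rel < 1e-4, f"{name}[{i}]: fd={fd} an={an} rel={rel}"
            checked += 1
    assert checked >= 40
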