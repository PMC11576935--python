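import numpy as np
import pytest

from discus import (
    DiscusNet,
    NetworkConfig,
    assembly_concat,
    count_parameters,
    masked_max_pool,
)


def random_batch(rng, B, P, min_obs=5):
    q = rng.standard_normal((B, P, 3)).astype(np.float32)
    s = rng.uniform(0.1, 1.0, (B, P)).astype(np.float32)
    mask = rng.uniform(size=(B, P)) < 0.6
    for b in range(B):
        while mask[b].sum() < min_obs:
            mask[b, rng.integers(P)] = True
    return q, s, mask


class TestSignInvariance:
    def test_bit_exact_symmetry_random_weights(self):
        """SI(q) = SI(-q) exactly, for arbitrary weights over many trials."""
        for trial in range(100):
            net = DiscusNet(NetworkConfig(width=16, si_hidden_layers=2), seed=trial)
            q = np.random.default_rng(trial).standard_normal((5, 3))
            a = net.sign_invariant_features(q)
            b = net.sign_invariant_features(-q)
            assert np.array_equal(a, b)

    def test_zero_input_doubles_branch(self, default_net):
        out = default_net.sign_invariant_features(np.zeros((1, 3)))
        # SI(0) = branch(0) + branch(0)
        assert np.all(out >= 0)  # ReLU output
        half = out / 2
        np.testing.assert_array_equal(half * 2, out)

    def test_output_width(self, default_net):
        out = default_net.sign_invariant_features(np.ones((4, 3)))
        assert out.shape == (4, 128)


class TestMaskedMaxPool:
    def test_hand_example(self):
        features = np.array([[[1.0, 5.0], [3.0, 2.0]]])
        mask = np.array([[True, True]])
        np.testing.assert_array_equal(masked_max_pool(features, mask), [[3.0, 5.0]])

    def test_mask_equals_deletion(self, rng):
        features = rng.standard_normal((1, 6, 4))
        mask = np.array([[True, False, True, True, False, True]])
        pooled = masked_max_pool(features, mask)
        subset = features[:, mask[0]]
        np.testing.assert_array_equal(
            pooled, masked_max_pool(subset, np.ones((1, 4), bool))
        )

    def test_permutation_invariant(self, rng):
        features = rng.standard_normal((2, 8, 3))
        mask = np.ones((2, 8), bool)
        perm = rng.permutation(8)
        np.testing.assert_array_equal(
            masked_max_pool(features, mask),
            masked_max_pool(features[:, perm], mask[:, perm]),
        )

    def test_vacuous_path_cannot_influence(self, rng):
        features = rng.standard_normal((1, 5, 3))
        mask = np.array([[True, True, False, True, True]])
        pooled = masked_max_pool(features, mask)
        features[0, 2] = 1e30  # masked path, arbitrarily large
        np.testing.assert_array_equal(pooled, masked_max_pool(features, mask))

    def test_all_false_row_rejected(self):
        with pytest.raises(ValueError):
            masked_max_pool(np.zeros((1, 3, 2)), np.zeros((1, 3), bool))


class TestAssemblyConcat:
    def test_width_sum(self, rng):
        out = assembly_concat(rng.standard_normal((2, 5, 128)), rng.standard_normal((2, 128)))
        assert out.shape == (2, 5, 256)

    def test_global_identical_across_paths(self, rng):
        g = rng.standard_normal((1, 7))
        out = assembly_concat(rng.standard_normal((1, 4, 3)), g)
        for p in range(4):
            np.testing.assert_array_equal(out[0, p, 3:], g[0])

    def test_batch_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            assembly_concat(rng.standard_normal((2, 4, 3)), rng.standard_normal((3, 7)))


class TestEncoder:
    def test_permutation_invariance_inference_exact(self, default_net):
        rng = np.random.default_rng(0)
        for _ in range(100):
            N = int(rng.integers(5, 40))
            q = rng.standard_normal((N, 3)).astype(np.float32)
            s = rng.uniform(0.1, 1.0, N).astype(np.float32)
            z = default_net.encode(q, s)
            perm = rng.permutation(N)
            assert np.array_equal(z, default_net.encode(q[perm], s[perm]))

    def test_sign_flip_invariance(self, default_net, rng):
        q = rng.standard_normal((12, 3)).astype(np.float32)
        s = rng.uniform(0.1, 1.0, 12).astype(np.float32)
        flip = rng.uniform(size=12) < 0.5
        q2 = q.copy()
        q2[flip] *= -1
        assert np.array_equal(default_net.encode(q, s), default_net.encode(q2, s))

    def test_latent_dimension_default(self, default_net, rng):
        q, s, _ = random_batch(rng, 1, 10)
        assert default_net.encode(q[0], s[0]).shape == (16,)

    def test_mask_equals_physical_subset(self, default_net, rng):
        q, s, mask = random_batch(rng, 4, 20)
        z_masked = default_net.encode(q, s, mask)
        for b in range(4):
            z_sub = default_net.encode(q[b][mask[b]], s[b][mask[b]])
            np.testing.assert_array_equal(z_masked[b], z_sub)

    def test_vacuous_path_safety(self, default_net, rng):
        q, s, mask = random_batch(rng, 2, 15)
        z = default_net.encode(q, s, mask)
        q2, s2 = q.copy(), s.copy()
        off = ~mask
        q2[off] = rng.standard_normal((off.sum(), 3)) * 100
        s2[off] = 7.7
        np.testing.assert_array_equal(z, default_net.encode(q2, s2, mask))

    def test_too_few_observations_rejected(self, default_net, rng):
        q, s, _ = random_batch(rng, 1, 4, min_obs=1)
        with pytest.raises(ValueError, match="at least 5"):
            default_net.encode(q[0], s[0])

    def test_non_finite_signals_rejected(self, default_net, rng):
        q, s, _ = random_batch(rng, 1, 8)
        s[0, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            default_net.encode(q[0], s[0])

    def test_training_mode_permutation_within_tolerance(self, rng):
        """Training-mode normalization pools over a permutation-invariant set,
        so latent codes agree to float accumulation order."""
        net = DiscusNet(NetworkConfig(), seed=3, dtype=np.float64)
        q, s, mask = random_batch(rng, 6, 20)
        z = net.encode(q.astype(np.float64), s.astype(np.float64), mask, training=True)
        perm = rng.permutation(20)
        z2 = net.encode(
            q[:, perm].astype(np.float64), s[:, perm].astype(np.float64), mask[:, perm],
            training=True,
        )
        np.testing.assert_allclose(z, z2, rtol=1e-6)


class TestDecoder:
    def test_antipodal_symmetry_exact(self, default_net, rng):
        z = rng.standard_normal(16).astype(np.float32)
        q = rng.standard_normal((9, 3)).astype(np.float32)
        np.testing.assert_array_equal(default_net.decode(q, z), default_net.decode(-q, z))

    def test_query_independence(self, default_net, rng):
        z = rng.standard_normal(16).astype(np.float32)
        q = rng.standard_normal((7, 3)).astype(np.float32)
        joint = default_net.decode(q, z)
        single = np.array([default_net.decode(q[i : i + 1], z)[0] for i in range(7)])
        np.testing.assert_allclose(joint, single, rtol=1e-6, atol=1e-7)

    @pytest.mark.parametrize("M", [1, 2, 30])
    def test_arbitrary_query_count(self, default_net, rng, M):
        z = rng.standard_normal(16).astype(np.float32)
        out = default_net.decode(rng.standard_normal((M, 3)).astype(np.float32), z)
        assert out.shape == (M,) and np.all(np.isfinite(out))


class TestReconstruct:
    def test_combined_invariance(self, default_net, rng):
        q, s, _ = random_batch(rng, 1, 15)
        query = rng.standard_normal((4, 3)).astype(np.float32)
        base = default_net.reconstruct(q[0], s[0], query)
        perm = rng.permutation(15)
        flip = np.where(rng.uniform(size=15) < 0.5, -1.0, 1.0)[:, None].astype(np.float32)
        alt = default_net.reconstruct(q[0][perm] * flip[perm], s[0][perm], -query)
        np.testing.assert_allclose(base, alt, rtol=1e-6, atol=1e-7)

    def test_minimal_case(self, default_net, rng):
        q, s, _ = random_batch(rng, 1, 5)
        out = default_net.reconstruct(q[0], s[0], rng.standard_normal((1, 3)).astype(np.float32))
        assert out.shape == (1,) and np.isfinite(out[0])

    @pytest.mark.parametrize("N,M", [(5, 1), (17, 8), (90, 30)])
    def test_flexible_cardinality(self, default_net, rng, N, M):
        q = rng.standard_normal((N, 3)).astype(np.float32)
        s = rng.uniform(0.1, 1.0, N).astype(np.float32)
        query = rng.standard_normal((M, 3)).astype(np.float32)
        assert default_net.reconstruct(q, s, query).shape == (M,)


class TestForwardPathsContract:
    def test_masked_forward_equals_subset_forward(self, default_net, rng):
        """Padded+masked batch forward agrees with per-voxel subset encoding."""
        q, s, mask = random_batch(rng, 3, 12)
        preds = default_net.forward_paths(q, s, mask)
        for b in range(3):
            z = default_net.encode(q[b][mask[b]], s[b][mask[b]])
            np.testing.assert_allclose(
                preds[b], default_net.decode(q[b], z), rtol=1e-6, atol=1e-7
            )


class TestParameterCount:
    def test_single_linear_layer_closed_form(self):
        cfg = NetworkConfig(
            width=10, latent_dim=2, si_hidden_layers=0, transform_hidden_layers=0,
            decoder_hidden_layers=0, encoder_stages=1,
        )
        # SI: 3→10; stage0: 11→2 (+BN none affine); decoder: 12→1
        expected = (3 * 10 + 10) + (11 * 2 + 2) + (12 * 1 + 1)
        assert count_parameters(cfg) == expected

    def test_affine_adds_two_per_norm_feature(self):
        base = NetworkConfig(width=6, latent_dim=2, encoder_stages=1)
        affine = NetworkConfig(width=6, latent_dim=2, encoder_stages=1, norm_affine=True)
        # one stage: hidden layers at width 6 + output at latent 2
        extra = 2 * (6 + 6 + 2)
        assert count_parameters(affine) - count_parameters(base) == extra

    def test_default_config_near_170k(self):
        n = count_parameters(NetworkConfig())
        assert 153_000 <= n <= 187_000

    def test_count_matches_instantiated(self, tiny_config):
        net = DiscusNet(tiny_config, seed=0)
        assert net.n_parameters() == count_parameters(tiny_config)


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_config):
        net = DiscusNet(tiny_config, seed=0, dtype=np.float64)
        rng = np.random.default_rng(1)
        B, P = 3, 9
        q = rng.standard_normal((B, P, 3))
        s = rng.uniform(0.2, 1.0, (B, P))
        mask = rng.uniform(size=(B, P)) < 0.7
        for b in range(B):
            while mask[b].sum() < 5:
                mask[b, rng.integers(P)] = True
        targets = rng.uniform(0.2, 1.0, (B, P))

        def loss():
            p, _ = net.forward_paths(q, s, mask, training=True)
            return 0.5 * np.sum((p - targets) ** 2)

        preds, cache = net.forward_paths(q, s, mask, training=True)
        grads = net.backward_paths(preds - targets, cache)
        eps = 1e-6
        for name in sorted(net.params):
            p, g = net.params[name], grads[name]
            for _ in range(3):
                ix = tuple(rng.integers(d) for d in p.shape)
                old = p[ix]
                p[ix] = old + eps
                lp = loss()
                p[ix] = old - eps
                lm = loss()
                p[ix] = old
                fd = (lp - lm) / (2 * eps)
                if abs(fd) < 1e-7 and abs(g[ix]) < 1e-7:
                    continue  # dead parameter (e.g. bias absorbed by normalization)
                assert abs(fd - g[ix]) / max(abs(fd), abs(g[ix])) < 1e-4, name


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, tiny_config, rng):
        net = DiscusNet(tiny_config, seed=2)
        path = tmp_path / "ckpt.npz"
        net.save(path)
        back = DiscusNet.load(path)
        assert back.config == net.config
        q, s, _ = random_batch(rng, 1, 8)
        np.testing.assert_array_equal(
            net.encode(q[0], s[0]), back.encode(q[0], s[0])
        )
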