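"""Neighbor-topology branch: functional ops, CNN geometry, model consistency."""

import numpy as np
import pytest

from napred import _tensor as T
from napred.topology_branch import (CNNConfig, TopologyBranch, branch1_score,
                                    build_pair_matrix, cnn_encode,
                                    mean_aggregate, project_fc,
                                    scale_attention, softmax_np,
                                    topology_attention)

RNG = np.random.default_rng(42)


class TestMeanAggregate:
    @pytest.mark.parametrize("vecs, expected", [
        ([(1, 0, 1)], (1, 0, 1)),
        ([(1, 0), (0, 1)], (0.5, 0.5)),
        ([(2, 4), (4, 8), (0, 0)], (2, 4)),
    ])
    def test_values(self, vecs, expected):
        assert np.array_equal(mean_aggregate(vecs), np.asarray(expected, float))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mean_aggregate([])


class TestProjectFC:
    def test_identity_passthrough(self):
        h = np.array([1.0, 2.0, 0.0])
        assert np.array_equal(project_fc(h, np.eye(3), np.zeros(3)), h)

    def test_relu_kills_negative(self):
        out = project_fc(np.array([2.0, 3.0]), np.array([[1.0, -1.0]]),
                         np.zeros(1))
        assert np.array_equal(out, np.zeros(1))
        assert np.array_equal(
            project_fc(np.ones(2), -np.eye(2), np.zeros(2)), np.zeros(2))

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            project_fc(np.array([np.nan]), np.eye(1), np.zeros(1))


class TestAttention:
    def test_identical_features_get_uniform_weights(self):
        u = RNG.normal(size=4)
        W, b, h = RNG.normal(size=(4, 4)), RNG.normal(size=4), RNG.normal(size=4)
        out, alpha = scale_attention([u, u, u], W, b, h)
        assert np.allclose(alpha, 1 / 3)
        assert np.allclose(out, u)

    def test_singleton_is_identity(self):
        u = RNG.normal(size=3)
        out, alpha = scale_attention([u], np.zeros((3, 3)), np.zeros(3),
                                     np.ones(3))
        assert np.allclose(alpha, [1.0])
        assert np.allclose(out, u)

    def test_hand_computed_scale_weights(self):
        # scores (ln2, 0) -> softmax (2/3, 1/3)
        u1 = np.array([np.arctanh(np.log(2.0))])
        u2 = np.array([0.0])
        out, alpha = scale_attention([u1, u2], np.eye(1), np.zeros(1),
                                     np.ones(1))
        assert np.allclose(alpha, [2 / 3, 1 / 3])
        assert np.allclose(out, 2 / 3 * u1 + 1 / 3 * u2)

    def test_hand_computed_topology_weights(self):
        # scores (ln3, 0) with h=2: tanh(w) = ln3/2
        u_R = np.array([np.arctanh(np.log(3.0) / 2.0)])
        u_D = np.array([0.0])
        out, alpha = topology_attention(u_R, u_D, np.eye(1), np.zeros(1),
                                        np.array([2.0]))
        assert np.allclose(alpha, [0.75, 0.25])
        assert np.allclose(out, 0.75 * u_R)

    def test_topology_symmetric_case(self):
        u = RNG.normal(size=5)
        W, b, h = RNG.normal(size=(5, 5)), RNG.normal(size=5), RNG.normal(size=5)
        out, alpha = topology_attention(u, u, W, b, h)
        assert np.allclose(alpha, [0.5, 0.5])
        assert np.allclose(out, u)

    def test_weights_sum_to_one_over_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            d = int(rng.integers(1, 6))
            K = int(rng.integers(1, 5))
            us = [rng.normal(size=d) for _ in range(K)]
            _, a1 = scale_attention(us, rng.normal(size=(d, d)),
                                    rng.normal(size=d), rng.normal(size=d))
            _, a2 = topology_attention(us[0], us[-1],
                                       rng.normal(size=(d, d)),
                                       rng.normal(size=d), rng.normal(size=d))
            assert abs(a1.sum() - 1.0) < 1e-6
            assert abs(a2.sum() - 1.0) < 1e-6
            assert ((a2 > 0) & (a2 < 1)).all()


class TestPairMatrix:
    def test_direct_assembly(self):
        u_r = [np.full(2, m) for m in (1, 2, 3)]
        u_d = [RNG.normal(size=2) for _ in range(3)]
        S = build_pair_matrix(u_r, u_d)
        assert S.shape == (2, 6)
        assert np.array_equal(S[0], [1, 1, 2, 2, 3, 3])
        assert np.array_equal(S[1], np.concatenate(u_d))

    def test_network_order_is_significant(self):
        u = [np.array([m, 0.0]) for m in (1, 2, 3)]
        S1 = build_pair_matrix(u, u)
        S2 = build_pair_matrix(u[::-1], u)
        assert not np.array_equal(S1, S2)

    def test_dimension_mismatch_raises(self):
        good = [np.zeros(3)] * 3
        with pytest.raises(ValueError):
            build_pair_matrix(good, [np.zeros(3), np.zeros(3), np.zeros(4)])
        with pytest.raises(ValueError):
            build_pair_matrix(good[:2], good)


class TestCNNEncode:
    def test_default_geometry_n_f_4(self):
        cfg = CNNConfig()
        ch, cw, ph, pw, z = cfg.out_dims(4)
        assert (ch, cw) == (3, 13)
        assert (ph, pw) == (2, 12)
        assert z == 16 * 2 * 12 == 384
        S = RNG.normal(size=(2, 12))
        W = RNG.normal(size=(16, 1, 2, 2))
        out = cnn_encode(S, cfg, W, np.zeros(16))
        assert out.shape == (384,)
        assert (out >= 0).all()

    def test_closed_form_dims_on_random_configs(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n_f = int(rng.integers(2, 9))
            cfg = CNNConfig(n_conv=int(rng.integers(1, 8)),
                            conv_kernel=(int(rng.integers(1, 4)),
                                         int(rng.integers(1, 4))),
                            pool_kernel=(int(rng.integers(1, 3)),
                                         int(rng.integers(1, 3))))
            wl, wh = cfg.conv_kernel
            we, wb = cfg.pool_kernel
            expect_h = (4 - wl + 1) - we + 1
            expect_w = (2 + 3 * n_f - wh + 1) - wb + 1
            if expect_h < 1 or expect_w < 1:
                continue
            *_, z = cfg.out_dims(n_f)
            assert z == cfg.n_conv * expect_h * expect_w
            W = rng.normal(size=(cfg.n_conv, 1, wl, wh))
            out = cnn_encode(rng.normal(size=(2, 3 * n_f)), cfg, W,
                             np.zeros(cfg.n_conv))
            assert out.shape == (z,)

    def test_zero_input_zero_bias_gives_zero(self):
        cfg = CNNConfig()
        out = cnn_encode(np.zeros((2, 9)), cfg,
                         RNG.normal(size=(16, 1, 2, 2)), np.zeros(16))
        assert np.array_equal(out, np.zeros_like(out))

    def test_oversized_kernel_raises(self):
        with pytest.raises(ValueError):
            CNNConfig(conv_kernel=(7, 2)).out_dims(4)


class TestBranch1Score:
    def test_symmetric_logits(self):
        p = branch1_score(np.array([0.0]), np.zeros((2, 1)), np.zeros(2))
        assert np.allclose(p, [0.5, 0.5])

    def test_hand_computed_softmax(self):
        p = branch1_score(np.array([np.log(9.0)]),
                          np.array([[1.0], [0.0]]), np.zeros(2))
        assert np.allclose(p, [0.9, 0.1])

    def test_normalization(self):
        for _ in range(10):
            p = branch1_score(RNG.normal(size=4), RNG.normal(size=(2, 4)),
                              RNG.normal(size=2))
            assert p.sum() == pytest.approx(1.0, abs=1e-12)


def _tiny_branch(n_f=4, seed=0):
    attr_dims = {1: (5, 3), 2: (6, 3), 3: (4, 3)}
    branch = TopologyBranch(attr_dims, n_f=n_f, orders=(1, 2), seed=seed)
    rng = np.random.default_rng(seed + 1)
    n_nodes = 7  # 4 drugs + 3 diseases
    H = {m: {(tau, k): rng.random((n_nodes, dims[0] if tau == "R" else dims[1]))
             for tau in ("R", "D") for k in (1, 2)}
         for m, dims in attr_dims.items()}
    return branch, H


class TestTopologyBranchModel:
    def test_model_matches_functional_composition(self):
        """The trained-model forward equals the step-by-step functional path."""
        branch, H = _tiny_branch()
        p = {k: v.data for k, v in branch.params.items()}
        drug, disease = 2, 5
        u_r, u_d = [], []
        for m in (1, 2, 3):
            reps = {}
            for center, node in (("drug", drug), ("disease", disease)):
                fused = {}
                for tau in ("R", "D"):
                    feats = [project_fc(H[m][(tau, k)][node],
                                        p[f"W_proj_{m}_{tau}_{k}"],
                                        p[f"b_proj_{m}_{tau}_{k}"])
                             for k in (1, 2)]
                    fused[tau], _ = scale_attention(
                        feats, p[f"W_scale_{center}"], p[f"b_scale_{center}"],
                        p[f"h_scale_{center}"])
                reps[center], _ = topology_attention(
                    fused["R"], fused["D"], p[f"W_topo_{center}"],
                    p[f"b_topo_{center}"], p[f"h_topo_{center}"])
            u_r.append(reps["drug"])
            u_d.append(reps["disease"])
        S = build_pair_matrix(u_r, u_d)
        z = cnn_encode(S, branch.cnn, p["W_conv"], p["b_conv"])
        prob_functional = branch1_score(z, p["W_soft1"], p["b_soft1"])

        S_model = branch.pair_matrix(np.array([drug]), np.array([disease]), H)
        assert np.allclose(S_model.data[0, 0], S, atol=1e-12)
        logits = branch.logits(np.array([drug]), np.array([disease]), H)
        prob_model = softmax_np(logits.data[0])
        assert np.allclose(prob_model, prob_functional, atol=1e-12)

    def test_backprop_matches_finite_differences(self):
        branch, H = _tiny_branch(n_f=3, seed=3)
        drug_nodes = np.array([0, 1])
        disease_nodes = np.array([4, 6])
        labels = np.array([1, 0])

        def fn():
            return branch.loss(drug_nodes, disease_nodes, H, labels)

        sampled = [branch.params[k] for k in
                   ("W_conv", "h_scale_drug", "W_topo_disease", "W_soft1",
                    "W_proj_2_D_1", "b_proj_1_R_2")]
        assert T.grad_check(fn, sampled) < 1e-4

    def test_deterministic_fit_and_scores(self):
        results = []
        for _ in range(2):
            branch, H = _tiny_branch(seed=11)
            labels = np.array([1, 0, 1, 0])
            branch.fit(np.array([0, 1, 2, 3]), np.array([4, 5, 6, 4]), H,
                       labels, epochs=3, seed=5)
            results.append(branch.scores(np.array([0, 1]), np.array([5, 6]), H))
        assert np.array_equal(results[0], results[1])

    def test_training_reduces_loss(self):
        branch, H = _tiny_branch(seed=2)
        labels = np.array([1, 0, 1, 0, 1, 0])
        hist = branch.fit(np.array([0, 1, 2, 3, 0, 2]),
                          np.array([4, 5, 6, 4, 6, 5]), H, labels,
                          epochs=30, seed=1)
        assert hist[-1] < hist[0]
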