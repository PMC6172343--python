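"""RBM energies and conditionals against exact enumeration; DBN training."""

import copy

import numpy as np
import pytest

from lspdbn import TrainConfig
from lspdbn import dbn


def random_machine(rng, n_vis=3, n_hid=2, scale=0.7):
    return dbn.RBMParams(weights=rng.normal(0, scale, (n_vis, n_hid)),
                         visible_bias=rng.normal(0, scale, n_vis),
                         hidden_bias=rng.normal(0, scale, n_hid))


class TestEnergyAndProbability:
    def test_hand_computed_energy(self):
        params = dbn.RBMParams(weights=np.array([[2.0]]),
                               visible_bias=np.array([0.5]),
                               hidden_bias=np.array([0.25]))
        assert dbn.rbm_energy(np.array([1.0]), np.array([1.0]), params) == -2.75

    def test_zero_params_zero_energy(self):
        params = dbn.RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        for v in dbn._all_states(3):
            for h in dbn._all_states(2):
                assert dbn.rbm_energy(v, h, params) == 0.0

    def test_energy_additive_over_independent_blocks(self):
        # block-diagonal weights: energy of the joint machine is the sum of
        # the two independent single-unit machines (brute force over states)
        rng = np.random.default_rng(0)
        w1, w2 = rng.normal(size=2)
        b = rng.normal(size=2)
        a = rng.normal(size=2)
        big = dbn.RBMParams(np.diag([w1, w2]), b, a)
        m1 = dbn.RBMParams(np.array([[w1]]), b[:1], a[:1])
        m2 = dbn.RBMParams(np.array([[w2]]), b[1:], a[1:])
        for v in dbn._all_states(2):
            for h in dbn._all_states(2):
                assert dbn.rbm_energy(v, h, big) == pytest.approx(
                    dbn.rbm_energy(v[:1], h[:1], m1)
                    + dbn.rbm_energy(v[1:], h[1:], m2))

    def test_uniform_partition_function(self):
        params = dbn.RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        assert dbn.partition_function(params) == pytest.approx(2**5)
        assert dbn.joint_prob(params, np.zeros(3), np.zeros(2)) == pytest.approx(2**-5)

    def test_joint_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        params = random_machine(rng)
        total = sum(dbn.joint_prob(params, v, h)
                    for v in dbn._all_states(3) for h in dbn._all_states(2))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_oversized_machine_refused(self):
        params = dbn.RBMParams(np.zeros((15, 15)), np.zeros(15), np.zeros(15))
        with pytest.raises(ValueError):
            dbn.partition_function(params)


class TestConditionals:
    def test_zero_params_give_half(self):
        params = dbn.RBMParams(np.zeros((4, 3)), np.zeros(4), np.zeros(3))
        assert np.allclose(dbn.prob_h_given_v(params, np.ones(4)), 0.5)
        assert np.allclose(dbn.prob_v_given_h(params, np.ones(3)), 0.5)

    def test_saturation(self):
        params = dbn.RBMParams(np.zeros((2, 2)), np.zeros(2),
                               np.array([10.0, -10.0]))
        p = dbn.prob_h_given_v(params, np.zeros(2))
        assert p[0] > 0.9999 and p[1] < 0.0001

    def test_match_enumeration_conditionals(self):
        # oracle: conditional from the enumerated joint distribution
        rng = np.random.default_rng(2)
        for _ in range(10):
            params = random_machine(rng)
            H = dbn._all_states(2)
            for v in dbn._all_states(3):
                weights = np.array([np.exp(-dbn.rbm_energy(v, h, params))
                                    for h in H])
                weights /= weights.sum()
                marginal = weights @ H
                np.testing.assert_allclose(dbn.prob_h_given_v(params, v),
                                           marginal, atol=1e-10)


class TestExactGradient:
    def test_matches_brute_force_enumeration(self):
        # route A (implementation): sigmoid conditionals for the data term,
        # vectorized enumeration for the model term; route B (oracle): both
        # terms by explicit state sums
        rng = np.random.default_rng(3)
        params = random_machine(rng)
        data = (rng.random((15, 3)) < 0.5).astype(float)
        gW, gvb, ghb = dbn.exact_loglik_grad(params, data)
        V, H = dbn._all_states(3), dbn._all_states(2)
        gW_o = np.zeros((3, 2)); gvb_o = np.zeros(3); ghb_o = np.zeros(2)
        for v in data:
            w = np.array([np.exp(-dbn.rbm_energy(v, h, params)) for h in H])
            w /= w.sum()
            gW_o += np.outer(v, w @ H); gvb_o += v; ghb_o += w @ H
        gW_o /= len(data); gvb_o /= len(data); ghb_o /= len(data)
        joint = np.array([[np.exp(-dbn.rbm_energy(v, h, params)) for h in H]
                          for v in V])
        joint /= joint.sum()
        for i, v in enumerate(V):
            for j, h in enumerate(H):
                gW_o -= joint[i, j] * np.outer(v, h)
                gvb_o -= joint[i, j] * v
                ghb_o -= joint[i, j] * h
        np.testing.assert_allclose(gW, gW_o, atol=1e-10)
        np.testing.assert_allclose(gvb, gvb_o, atol=1e-10)
        np.testing.assert_allclose(ghb, ghb_o, atol=1e-10)


class TestContrastiveDivergence:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        params = random_machine(rng, 4, 3)
        batch = (np.random.default_rng(5).random((10, 4)) < 0.5).astype(float)
        cfg = TrainConfig(seed=11)
        a = dbn.cd_update(params, batch, cfg)
        b = dbn.cd_update(params, batch, cfg)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_cd_direction_tracks_exact_gradient(self):
        # CD-50 update direction vs the enumerated log-likelihood gradient
        cfg = TrainConfig(cd_steps=50, lr_weights=1.0, lr_biases=1.0)
        rng = np.random.default_rng(6)
        cosines = []
        for _ in range(50):
            params = random_machine(rng)
            batch = (rng.random((30, 3)) < rng.random(3)).astype(float)
            g = dbn.exact_loglik_grad(params, batch)
            exact = np.concatenate([g[0].ravel(), g[1], g[2]])
            new = dbn.cd_update(params, batch, cfg, rng)
            step = np.concatenate([(new.weights - params.weights).ravel(),
                                   new.visible_bias - params.visible_bias,
                                   new.hidden_bias - params.hidden_bias])
            cosines.append(exact @ step
                           / (np.linalg.norm(exact) * np.linalg.norm(step)))
        assert np.mean(cosines) > 0.9

    def test_invalid_batches_rejected(self):
        params = random_machine(np.random.default_rng(7))
        cfg = TrainConfig()
        with pytest.raises(ValueError):
            dbn.cd_update(params, np.empty((0, 3)), cfg)
        with pytest.raises(ValueError):
            dbn.cd_update(params, np.full((2, 3), 1.5), cfg)


class TestPretrain:
    def test_layer_shapes(self):
        rng = np.random.default_rng(8)
        data = rng.random((40, 256))
        cfg = TrainConfig(pretrain_epochs=1, batch_size=20, seed=0)
        model = dbn.pretrain((256, 60, 50, 35), data, cfg)
        shapes = [(r.n_visible, r.n_hidden) for r in model.rbms]
        assert shapes == [(256, 60), (60, 50), (50, 35)]
        assert model.softmax_weights.shape == (35, 3)

    def test_zero_epochs_returns_seeded_init(self):
        rng = np.random.default_rng(9)
        data = rng.random((20, 8))
        cfg = TrainConfig(pretrain_epochs=0, seed=42)
        a = dbn.pretrain((8, 4, 3), data, cfg)
        b = dbn.pretrain((8, 4, 3), data, cfg)
        np.testing.assert_array_equal(a.rbms[0].weights, b.rbms[0].weights)
        assert not a.pretrained

    def test_reconstruction_error_decreases_on_bimodal_data(self):
        # two clusters of binary patterns; CD should reduce reconstruction
        # error over the first epochs in the overwhelming majority of seeds
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            proto = np.array([[1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]], float)
            data = proto[rng.integers(0, 2, 80)]
            flip = rng.random(data.shape) < 0.05
            data = np.abs(data - flip)
            cfg = TrainConfig(pretrain_epochs=5, batch_size=20,
                              lr_weights=0.5, lr_biases=0.25, seed=seed)
            _, history = dbn.train_rbm(data, 3, cfg, rng)
            wins += history[-1] < history[0]
        assert wins >= 90


class TestFinetune:
    def make_toy(self, rng):
        # three well-separated 2-D classes
        centers = np.array([[0.1, 0.1], [0.9, 0.1], [0.5, 0.9]])
        y = rng.integers(0, 3, 120)
        X = np.clip(centers[y] + rng.normal(0, 0.05, (120, 2)), 0, 1)
        return X, y

    def test_loss_decreases_on_separable_toy(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X, y = self.make_toy(rng)
            cfg = TrainConfig(pretrain_epochs=10, finetune_epochs=40,
                              batch_size=120, finetune_lr=0.5, lr_decay=1.0,
                              seed=seed)
            model = dbn.fit_dbn(X, y, (8, 6, 4), cfg)
            assert model.loss_history[-1] < model.loss_history[0]

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(10)
        cfg = TrainConfig(pretrain_epochs=0, seed=3)
        model = dbn.pretrain((4, 3, 2, 2), rng.random((12, 4)), cfg)
        for i, r in enumerate(model.rbms):
            model.rbms[i] = dbn.RBMParams(
                r.weights + rng.normal(0, 0.3, r.weights.shape),
                r.visible_bias, r.hidden_bias + rng.normal(0, 0.2, r.hidden_bias.shape))
        model.softmax_weights = rng.normal(0, 0.3, model.softmax_weights.shape)
        X = rng.random((12, 4))
        y = rng.integers(0, 3, 12)
        loss, g_rbm, g_sw, g_sb = dbn._loss_and_grads(model, X, y, cfg)
        eps = 1e-6

        def fd(mutate):
            up = copy.deepcopy(model); mutate(up, +eps)
            dn = copy.deepcopy(model); mutate(dn, -eps)
            lu = dbn._loss_and_grads(up, X, y, cfg)[0]
            ld = dbn._loss_and_grads(dn, X, y, cfg)[0]
            return (lu - ld) / (2 * eps)

        for li in range(3):
            w = model.rbms[li].weights
            for idx in [(0, 0), (w.shape[0] - 1, w.shape[1] - 1)]:
                def mut(m, d, li=li, idx=idx):
                    w2 = m.rbms[li].weights.copy()
                    w2[idx] += d
                    m.rbms[li] = dbn.RBMParams(w2, m.rbms[li].visible_bias,
                                               m.rbms[li].hidden_bias)
                assert abs(fd(mut) - g_rbm[li][0][idx]) <= 1e-5 * max(
                    1e-4, abs(g_rbm[li][0][idx]))

        def mut_sw(m, d):
            m.softmax_weights = m.softmax_weights.copy()
            m.softmax_weights[0, 1] += d
        assert fd(mut_sw) == pytest.approx(g_sw[0, 1], rel=1e-5)

    def test_huge_weight_decay_shrinks_softmax_weights(self):
        rng = np.random.default_rng(11)
        X, y = self.make_toy(rng)
        base = TrainConfig(pretrain_epochs=2, finetune_epochs=50,
                           batch_size=40, finetune_lr=0.5, seed=1)
        big = TrainConfig(pretrain_epochs=2, finetune_epochs=50,
                          batch_size=40, finetune_lr=0.5, weight_decay=5.0,
                          seed=1)
        m_base = dbn.fit_dbn(X, y, (6, 4, 3), base)
        m_big = dbn.fit_dbn(X, y, (6, 4, 3), big)
        assert (np.abs(m_big.softmax_weights).max()
                < 0.05 * np.abs(m_base.softmax_weights).max())
        # with the output weights crushed, predictions carry only the class
        # priors (the bias is not decayed), i.e. near-uniform
        probs = dbn.predict_proba(m_big, X)
        np.testing.assert_allclose(probs, 1 / 3, atol=0.1)


class TestPredict:
    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(12)
        cfg = TrainConfig(pretrain_epochs=0, seed=2)
        model = dbn.pretrain((5, 4, 3), rng.random((10, 5)), cfg)
        probs = dbn.predict_proba(model, rng.random((7, 5)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_three_output_units_for_three_classes(self):
        cfg = TrainConfig(pretrain_epochs=0)
        model = dbn.pretrain((6, 4, 3), np.random.default_rng(0).random((8, 6)),
                             cfg, class_count=3)
        assert model.softmax_weights.shape[1] == 3

    def test_tie_breaks_to_lowest_index(self):
        model = dbn.DBNModel(rbms=[], softmax_weights=np.zeros((2, 3)),
                             softmax_bias=np.zeros(3), layer_sizes=(2,),
                             class_count=3)
        labels = dbn.predict(model, np.random.default_rng(1).random((5, 2)))
        assert np.all(labels == 0)

    def test_wrong_dimension_rejected(self):
        cfg = TrainConfig(pretrain_epochs=0)
        model = dbn.pretrain((6, 4, 3), np.random.default_rng(0).random((8, 6)), cfg)
        with pytest.raises(ValueError):
            dbn.predict(model, np.ones((2, 5)))


class TestGridSearch:
    def test_single_candidate_is_best(self):
        rng = np.random.default_rng(13)
        X = rng.random((40, 6))
        y = rng.integers(0, 3, 40)
        cfg = TrainConfig(pretrain_epochs=1, finetune_epochs=2, batch_size=20)
        best, table = dbn.grid_search_structure(X, y, [(5, 4, 3)], k=4,
                                                seed=0, config=cfg)
        assert best == (5, 4, 3)
        assert len(table) == 1

    def test_default_search_space_is_the_coordinate_grid(self):
        grid = dbn.DEFAULT_STRUCTURE_GRID
        assert len(grid) == 18
        assert {g[0] for g in grid[:6]} == {15, 30, 45, 60, 75, 90}
        assert all(g[1:] == (50, 35) for g in grid[:6])
        assert {g[1] for g in grid[6:12]} == {10, 20, 30, 40, 50, 60}
        assert {g[2] for g in grid[12:]} == {25, 30, 35, 50, 70, 85}

    def test_cv_folds_deterministic_given_seed(self):
        from lspdbn import kfold_indices
        a = kfold_indices(40, 5, seed=9)
        b = kfold_indices(40, 5, seed=9)
        np.testing.assert_array_equal(a, b)
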