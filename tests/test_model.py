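"""GCN layers, corruption, readout, discriminator, losses and training."""

import numpy as np
import pytest

from sducl import (
    SDUCLModel,
    TrainConfig,
    build_knn_graph,
    contrastive_loss,
    corrupt,
    discover_microenvironments,
    discriminate,
    gcn_layer,
    readout,
    reconstruction_loss,
    train,
)
from sducl.diffusion import MicroenvironmentMap
from sducl.model import _sigmoid


def _small_problem(n=5, d=4, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.random((n, 2)) * 10
    g = build_knn_graph(coords, k=2)
    me = discover_microenvironments(g, alpha=0.1, n_sub=min(3, n))
    F = rng.standard_normal((n, d))
    return g, me, F


class TestGcnLayer:
    def test_isolated_node_identity_weights(self):
        out = gcn_layer(np.array([[2.0, -3.0]]), np.ones((1, 1)),
                        np.eye(2), np.zeros(2), "relu")
        np.testing.assert_array_equal(out, [[2.0, 0.0]])

    def test_symmetric_inputs_stay_symmetric(self, rng):
        A = np.full((2, 2), 0.5)
        H = np.tile(rng.standard_normal(3), (2, 1))
        out = gcn_layer(H, A, rng.standard_normal((3, 4)), np.zeros(4), "relu")
        np.testing.assert_allclose(out[0], out[1])

    def test_zero_weights_zero_output(self, rng):
        out = gcn_layer(rng.random((3, 2)), np.eye(3), np.zeros((2, 2)),
                        np.zeros(2), "relu")
        np.testing.assert_array_equal(out, 0.0)

    def test_linear_activation_allows_negatives(self):
        out = gcn_layer(np.array([[-1.0]]), np.ones((1, 1)), np.eye(1),
                        np.zeros(1), "linear")
        assert out[0, 0] == -1.0


class TestCorrupt:
    def test_rows_are_a_permutation(self, rng):
        F = rng.random((10, 3))
        Fp, _, _ = corrupt(F, None, rng)
        np.testing.assert_array_equal(
            np.sort(Fp, axis=0), np.sort(F, axis=0)
        )

    def test_single_row_unchanged(self, rng):
        F = rng.random((1, 3))
        Fp, _, _ = corrupt(F, None, rng)
        np.testing.assert_array_equal(Fp, F)

    def test_same_seed_same_permutation(self):
        F = np.arange(20.0).reshape(10, 2)
        Fp1, _, p1 = corrupt(F, None, np.random.default_rng(5))
        Fp2, _, p2 = corrupt(F, None, np.random.default_rng(5))
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(Fp1, Fp2)


class TestReadout:
    def _me(self, members):
        members = np.asarray(members)
        n = members.shape[0]
        return MicroenvironmentMap(
            members=members, signal=np.eye(n), alpha=0.1,
            n_sub=members.shape[1],
        )

    def test_identical_rows(self):
        h = np.array([1.0, -2.0])
        H = np.tile(h, (4, 1))
        me = self._me([[0, 1], [1, 2], [2, 3], [3, 0]])
        S = readout(H, me)
        np.testing.assert_allclose(S, np.tile(_sigmoid(h), (4, 1)))

    def test_zero_embeddings_give_half(self):
        me = self._me([[0, 1], [1, 0]])
        np.testing.assert_array_equal(readout(np.zeros((2, 3)), me), 0.5)

    def test_singleton_members(self, rng):
        H = rng.standard_normal((3, 4))
        me = self._me([[0], [1], [2]])
        np.testing.assert_allclose(readout(H, me), _sigmoid(H))


class TestDiscriminator:
    def test_zero_matrix_gives_half(self, rng):
        h, s = rng.standard_normal(4), rng.standard_normal(4)
        assert discriminate(h, s, np.zeros((4, 4))) == pytest.approx(0.5)

    def test_identity_unit_vectors(self):
        e1 = np.eye(4)[0]
        assert discriminate(e1, e1, np.eye(4)) == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-12
        )

    def test_bilinear_transpose_identity(self, rng):
        h, s = rng.standard_normal(4), rng.standard_normal(4)
        W = rng.standard_normal((4, 4))
        assert discriminate(h, s, W) == pytest.approx(
            discriminate(s, h, W.T), abs=1e-12
        )


class TestLosses:
    def test_zero_discriminator_gives_ln2(self, rng):
        H = rng.standard_normal((6, 4))
        Hp = rng.standard_normal((6, 4))
        S = rng.random((6, 4))
        l1, l2 = contrastive_loss(H, Hp, S, S, np.zeros((4, 4)))
        assert l1 == pytest.approx(np.log(2), abs=1e-12)
        assert l2 == pytest.approx(np.log(2), abs=1e-12)

    def test_perfect_discrimination_drives_loss_to_zero(self):
        # large positive logits for positives, large negative for negatives
        H = np.array([[10.0]])
        Hp = np.array([[-10.0]])
        S = np.array([[1.0]])
        l1, _ = contrastive_loss(H, Hp, S, S, np.eye(1) * 10)
        assert l1 < 1e-6

    def test_reconstruction_loss_examples(self):
        F = np.array([[1.0, 0.0]])
        assert reconstruction_loss(F, F) == 0.0
        assert reconstruction_loss(F, np.zeros((1, 2))) == pytest.approx(1.0)
        # quadratic homogeneity
        X = np.array([[0.5, 0.0]])
        l1 = reconstruction_loss(F, X)
        l2 = reconstruction_loss(2 * F, 2 * X)
        assert l2 == pytest.approx(4 * l1)


class TestGradients:
    def _loss_fn(self, model, F, A, M, perm):
        losses, grads = model.loss_and_grads(F, A, M, perm)
        return losses["L"], grads

    @pytest.mark.parametrize("param", ["Wd", "W1", "W2", "W3", "b2"])
    def test_analytic_matches_finite_difference(self, param):
        g, me, F = _small_problem(n=5, d=4, seed=3)
        cfg = TrainConfig(hidden_dim=6, embed_dim=3, seed=1)
        model = SDUCLModel(in_dim=4, config=cfg)
        A = g.A_hat_norm
        M = me.membership_matrix()
        perm = np.random.default_rng(0).permutation(5)
        _, grads = self._loss_fn(model, F, A, M, perm)
        eps = 1e-6
        P = model.params[param]
        num = np.zeros_like(P)
        for idx in np.ndindex(P.shape):
            orig = P[idx]
            P[idx] = orig + eps
            lp, _ = self._loss_fn(model, F, A, M, perm)
            P[idx] = orig - eps
            lm, _ = self._loss_fn(model, F, A, M, perm)
            P[idx] = orig
            num[idx] = (lp - lm) / (2 * eps)
        np.testing.assert_allclose(grads[param], num, atol=1e-4)

    def test_contrastive_gradient_zero_at_zero_discriminator(self):
        # with W_disc = 0 positives and negatives are indistinguishable:
        # loss sits at ln 2 and its W_disc-gradient vanishes by symmetry
        g, me, F = _small_problem(n=5, d=4, seed=2)
        cfg = TrainConfig(hidden_dim=6, embed_dim=3, alpha_rec=0.0, seed=1)
        model = SDUCLModel(in_dim=4, config=cfg)
        model.params["Wd"][:] = 0.0
        perm = np.arange(5)  # identity corruption => H' = H
        losses, grads = model.loss_and_grads(
            F, g.A_hat_norm, me.membership_matrix(), perm
        )
        assert losses["L_con"] == pytest.approx(np.log(2), abs=1e-12)
        np.testing.assert_allclose(grads["Wd"], 0.0, atol=1e-12)


class TestTraining:
    def test_both_losses_disabled_is_an_error(self):
        with pytest.raises(ValueError, match="training signal"):
            SDUCLModel(in_dim=4, config=TrainConfig(alpha_rec=0, beta_con=0))

    @pytest.mark.parametrize("ablation", [
        dict(beta_con=0.0),   # plain graph autoencoder
        dict(alpha_rec=0.0),  # contrastive-only (DGI-style)
    ])
    def test_single_objective_training_runs(self, ablation):
        g, me, F = _small_problem(n=12, d=6, seed=4)
        cfg = TrainConfig(hidden_dim=8, embed_dim=4, epochs=20, seed=0, **ablation)
        model = SDUCLModel(in_dim=6, config=cfg)
        result = model.fit(F, g.A_hat_norm, me)
        assert result.H.shape == (12, 4)
        assert np.all(np.isfinite(result.H))
        assert all(np.isfinite(rec["L"]) for rec in result.losses)

    def test_reconstruction_loss_decreases(self):
        g, me, F = _small_problem(n=20, d=8, seed=5)
        cfg = TrainConfig(hidden_dim=16, embed_dim=4, epochs=100, seed=0)
        model = SDUCLModel(in_dim=8, config=cfg)
        result = model.fit(F, g.A_hat_norm, me)
        assert result.losses[-1]["L_rec"] < result.losses[0]["L_rec"]

    def test_training_deterministic_given_seed(self):
        g, me, F = _small_problem(n=10, d=5, seed=6)
        outs = []
        for _ in range(2):
            cfg = TrainConfig(hidden_dim=8, embed_dim=4, epochs=15, seed=9)
            model = SDUCLModel(in_dim=5, config=cfg)
            outs.append(model.fit(F, g.A_hat_norm, me).H)
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_encoder_permutation_equivariance(self, rng):
        g, me, F = _small_problem(n=8, d=5, seed=7)
        cfg = TrainConfig(hidden_dim=6, embed_dim=3, seed=2)
        model = SDUCLModel(in_dim=5, config=cfg)
        perm = rng.permutation(8)
        A = g.A_hat_norm
        H1 = model.encode(F, A)[perm]
        H2 = model.encode(F[perm], A[np.ix_(perm, perm)])
        np.testing.assert_allclose(H1, H2, atol=1e-12)

    def test_whole_graph_readout_when_n_sub_is_n(self):
        # the "without signal diffusion" ablation: one global summary
        g, me, F = _small_problem(n=10, d=5, seed=8)
        me_all = discover_microenvironments(g, alpha=0.1, n_sub=10)
        cfg = TrainConfig(hidden_dim=6, embed_dim=3, seed=0)
        model = SDUCLModel(in_dim=5, config=cfg)
        H = model.encode(F, g.A_hat_norm)
        S = readout(H, me_all)
        np.testing.assert_allclose(S, np.tile(S[0], (10, 1)), atol=1e-12)

    def test_train_wrapper_returns_model_and_embeddings(self):
        g, me, F = _small_problem(n=10, d=5, seed=9)
        cfg = TrainConfig(hidden_dim=6, embed_dim=3, epochs=5, seed=0)
        model, result = train(F, g, me, cfg)
        assert result.H.shape == (10, 3)
        assert len(result.losses) == 5
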