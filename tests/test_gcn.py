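import numpy as np
import pytest
import scipy.sparse as sp

from brainlink import autodiff as ad
from brainlink import gcn
from brainlink.gcn import (
    ConvLayer,
    GCNHyper,
    GCNModel,
    bce_loss,
    chebyshev_filter,
    gcn_forward,
    init_gcn,
    normalized_laplacian,
    pair_embed,
    sae_encode,
    score_pairs,
    train,
    train_sae,
)
from brainlink.hetero import assemble_hetero


def _random_symmetric(n, rng, density=0.3):
    A = (rng.random((n, n)) < density) * rng.random((n, n))
    A = np.triu(A, 1)
    return A + A.T


class TestAutodiff:
    def test_gradients_match_finite_differences(self, rng):
        """One composite expression touching every op used by the models."""
        W = ad.parameter(rng.standard_normal((4, 3)))
        b = ad.parameter(rng.standard_normal(3))
        t = ad.parameter(np.array(0.7))
        X = ad.constant(rng.standard_normal((5, 4)))
        y = (rng.random((2, 1)) > 0.5).astype(float)
        Wfix = rng.standard_normal((6, 1))

        def forward(Wv, bv, tv):
            Wn, bn, tn = ad.Var(Wv), ad.Var(bv), ad.Var(np.array(tv))
            H = ad.relu(ad.add(ad.matmul(X, Wn), bn))
            H = ad.scale(H, tn)
            P = ad.softmax_rows(H)
            kl_bit = ad.smean(ad.mul(P, ad.log(P)))
            E = ad.concat_cols(ad.take_rows(H, np.array([0, 2])),
                               ad.take_rows(H, np.array([1, 1])))
            z = ad.matmul(E, ad.constant(Wfix))
            loss = ad.add(ad.sigmoid_bce_with_logits(z, y), kl_bit)
            return loss, (Wn, bn, tn)

        loss, (Wn, bn, tn) = forward(W.value, b.value, float(t.value))
        loss.backward()
        eps = 1e-6
        for var, name in ((Wn, "W"), (bn, "b"), (tn, "t")):
            g_num = np.zeros_like(var.value)
            it = np.nditer(var.value, flags=["multi_index"])
            while not it.finished:
                idx = it.multi_index
                for sgn in (1, -1):
                    pert = {k: v.copy() for k, v in
                            {"W": Wn.value, "b": bn.value, "t": tn.value}.items()}
                    pert[name][idx] += sgn * eps
                    lv, _ = forward(pert["W"], pert["b"], float(pert["t"]))
                    g_num[idx] += sgn * float(lv.value) / (2 * eps)
                it.iternext()
            np.testing.assert_allclose(var.grad, g_num, atol=1e-5)


class TestSAE:
    def test_identity_encoder_is_passthrough(self, rng):
        X = rng.random((6, 4))  # nonnegative
        params = gcn.SAEParams(c_sae=4)
        params.encoders["G"] = (np.eye(4), np.zeros(4))
        np.testing.assert_array_equal(sae_encode(X, params, "G"), X)

    def test_training_reduces_reconstruction_error(self, rng):
        X = rng.standard_normal((50, 20))
        _, hist = train_sae({"G": X}, c_sae=8, epochs=200, seed=11)
        assert hist["G"][-1] < hist["G"][0]

    def test_two_classes_share_output_width(self, rng):
        params, _ = train_sae(
            {"G": rng.random((10, 20)), "D": rng.random((4, 7))},
            c_sae=16, epochs=5, seed=0,
        )
        assert sae_encode(rng.random((10, 20)), params, "G").shape == (10, 16)
        assert sae_encode(rng.random((4, 7)), params, "D").shape == (4, 16)

    def test_dim_mismatch_rejected(self, rng):
        params, _ = train_sae({"G": rng.random((5, 6))}, c_sae=3, epochs=2, seed=0)
        with pytest.raises(ValueError, match="encoder input"):
            sae_encode(rng.random((5, 9)), params, "G")


class TestNormalizedLaplacian:
    def test_two_node_closed_form(self):
        op = normalized_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(op.laplacian.toarray(), [[1, -1], [-1, 1]])
        evals = np.linalg.eigvalsh(op.laplacian.toarray())
        np.testing.assert_allclose(sorted(evals), [0.0, 2.0], atol=1e-12)

    def test_isolated_node_convention(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        L = normalized_laplacian(A).laplacian.toarray()
        np.testing.assert_array_equal(L[2], [0.0, 0.0, 1.0])

    def test_eigenvalues_within_spectral_bound(self, rng):
        A = _random_symmetric(20, rng)
        op = normalized_laplacian(A)
        evals = np.linalg.eigvalsh(op.laplacian.toarray())
        assert evals.min() >= -1e-8 and evals.max() <= 2.0 + 1e-8
        assert op.lambda_max == pytest.approx(evals.max(), abs=1e-4)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            normalized_laplacian(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestChebyshevFilter:
    def test_theta0_is_identity(self, rng):
        op = normalized_laplacian(_random_symmetric(8, rng))
        X = rng.standard_normal((8, 3))
        np.testing.assert_allclose(
            chebyshev_filter(op, X, [1.0, 0.0, 0.0]), X, atol=1e-12
        )

    def test_theta1_is_scaled_laplacian(self, rng):
        op = normalized_laplacian(_random_symmetric(8, rng))
        X = rng.standard_normal((8, 3))
        Lt = (2.0 / op.lambda_max) * op.laplacian.toarray() - np.eye(8)
        np.testing.assert_allclose(
            chebyshev_filter(op, X, [0.0, 1.0]), Lt @ X, atol=1e-10
        )

    def test_path_graph_matches_spectral_evaluation(self, rng):
        n = 8
        A = np.zeros((n, n))
        for i in range(n - 1):
            A[i, i + 1] = A[i + 1, i] = 1.0
        op = normalized_laplacian(A)
        X = rng.standard_normal((n, 4))
        theta = rng.standard_normal(5)  # K = 4
        Lt = (2.0 / op.lambda_max) * op.laplacian.toarray() - np.eye(n)
        lam, U = np.linalg.eigh(Lt)
        # scalar Chebyshev recursion on the eigenvalues
        Tk = [np.ones_like(lam), lam]
        for _ in range(2, 5):
            Tk.append(2 * lam * Tk[-1] - Tk[-2])
        g = sum(theta[k] * Tk[k] for k in range(5))
        expected = U @ np.diag(g) @ U.T @ X
        np.testing.assert_allclose(
            chebyshev_filter(op, X, theta), expected, atol=1e-6
        )

    def test_nonpositive_lambda_max_rejected(self, rng):
        op = normalized_laplacian(_random_symmetric(5, rng))
        op.lambda_max = 0.0
        with pytest.raises(ValueError, match="lambda_max"):
            chebyshev_filter(op, np.eye(5), [1.0])


def _hetero_gd(A, n_genes):
    n = A.shape[0]
    vocabs = {"G": [f"g{i}" for i in range(n_genes)],
              "D": [f"d{i}" for i in range(n - n_genes)]}
    blocks = {
        ("G", "G"): A[:n_genes, :n_genes],
        ("G", "D"): A[:n_genes, n_genes:],
        ("D", "D"): A[n_genes:, n_genes:],
    }
    return assemble_hetero(blocks, ["G", "D"], vocabs)


def _manual_model(weights, mode, K=1):
    """A one-conv-layer linear model with prescribed weights."""
    h = weights.shape[1]
    hyper = GCNHyper(mode=mode, n_layers=1, hidden=h, K=K)
    return GCNModel(
        mode=mode, hyper=hyper,
        conv_layers=[ConvLayer(theta=np.r_[1.0, np.zeros(K)], W=weights,
                               b=np.zeros(h))],
        mlp_W1=np.zeros((2 * h, h)), mlp_b1=np.zeros(h),
        mlp_Wout=np.zeros((h, 1)), mlp_bout=np.zeros(1),
    )


class TestGCNForward:
    def test_two_node_hand_example(self):
        """One gene, one disease, one unit edge: with degrees taken from A
        alone, D^{-1/2}(I+A)D^{-1/2} = [[1,1],[1,1]], so X=I, W=I gives two
        rows of ones."""
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        model = _manual_model(np.eye(2), mode="simplified")
        H_G, H_D = gcn_forward(A, np.eye(2), model, n_genes=1)
        np.testing.assert_allclose(H_G, [[1.0, 1.0]], atol=1e-12)
        np.testing.assert_allclose(H_D, [[1.0, 1.0]], atol=1e-12)

    def test_zero_adjacency_keeps_self_signal(self, rng):
        X = rng.standard_normal((4, 3))
        W = rng.standard_normal((3, 3))
        model = _manual_model(W, mode="simplified")
        H_G, H_D = gcn_forward(np.zeros((4, 4)), X, model, n_genes=2)
        np.testing.assert_allclose(np.vstack([H_G, H_D]), X @ W, atol=1e-12)

    @pytest.mark.parametrize("mode", ["chebyshev", "simplified"])
    def test_matches_dense_reimplementation(self, rng, mode):
        n, n_genes, f = 30, 20, 6
        A = _random_symmetric(n, rng)
        X = rng.standard_normal((n, f))
        hyper = GCNHyper(mode=mode, hidden=5, K=3, n_layers=2)
        model = init_gcn(f, hyper, seed=4)
        H_G, H_D = gcn_forward(A, X, model, n_genes=n_genes)

        # straight-line dense oracle
        if mode == "chebyshev":
            op = normalized_laplacian(A)
            Lt = (2.0 / op.lambda_max) * op.laplacian.toarray() - np.eye(n)
            mats = [np.eye(n), Lt]
            for _ in range(2, 4):
                mats.append(2 * Lt @ mats[-1] - mats[-2])
        else:
            deg = A.sum(axis=1)
            dinv = np.where(deg > 0, 1 / np.sqrt(np.where(deg > 0, deg, 1)), 1.0)
            mats = [np.diag(dinv) @ (np.eye(n) + A) @ np.diag(dinv)]
        H = X
        for li, layer in enumerate(model.conv_layers):
            if mode == "chebyshev":
                S = sum(layer.theta[k] * mats[k] @ H for k in range(4))
            else:
                S = mats[0] @ H
            Z = S @ layer.W + layer.b
            H = np.maximum(Z, 0) if li < 1 else Z
        np.testing.assert_allclose(np.vstack([H_G, H_D]), H, atol=1e-6)


class TestPairEmbedAndScore:
    def test_single_pair_concatenation(self, rng):
        H_G, H_D = rng.random((3, 2)), rng.random((2, 2))
        row = pair_embed(H_G, H_D, [(1, 0)])
        np.testing.assert_array_equal(row, np.r_[H_G[1], H_D[0]][None])

    def test_duplicate_pairs_duplicate_rows(self, rng):
        H_G, H_D = rng.random((3, 2)), rng.random((2, 2))
        rows = pair_embed(H_G, H_D, [(0, 1), (0, 1)])
        np.testing.assert_array_equal(rows[0], rows[1])

    def test_empty_pair_list(self, rng):
        assert pair_embed(rng.random((3, 4)), rng.random((2, 4)), []).shape == (0, 8)

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(IndexError):
            pair_embed(rng.random((3, 2)), rng.random((2, 2)), [(5, 0)])

    def test_zero_mlp_scores_half(self, rng):
        model = _manual_model(np.eye(2), mode="simplified")
        scores = score_pairs(rng.random((4, 4)), model)
        np.testing.assert_allclose(scores, 0.5)

    def test_large_bias_saturates(self, rng):
        model = _manual_model(np.eye(2), mode="simplified")
        model.mlp_bout = np.array([10.0])
        assert (score_pairs(rng.random((4, 4)), model) > 0.999).all()

    def test_matches_manual_forward(self, rng):
        model = _manual_model(np.eye(3), mode="simplified")
        model.mlp_W1 = rng.standard_normal((6, 3))
        model.mlp_b1 = rng.standard_normal(3)
        model.mlp_Wout = rng.standard_normal((3, 1))
        model.mlp_bout = rng.standard_normal(1)
        H = rng.standard_normal((5, 6))
        expected = 1 / (1 + np.exp(-(
            np.maximum(H @ model.mlp_W1 + model.mlp_b1, 0)
            @ model.mlp_Wout + model.mlp_bout
        ).ravel()))
        np.testing.assert_allclose(score_pairs(H, model), expected, atol=1e-8)


class TestBCELoss:
    def test_perfect_prediction_near_zero(self):
        assert bce_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0])) <= 4e-12

    def test_hand_computed_contribution(self):
        assert bce_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(
            np.log(2.0), abs=1e-12
        )

    def test_permutation_invariance(self, rng):
        s = rng.random(20)
        y = (rng.random(20) > 0.5).astype(float)
        perm = rng.permutation(20)
        assert bce_loss(s, y) == pytest.approx(bce_loss(s[perm], y[perm]), abs=1e-9)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            bce_loss(np.array([0.5]), np.array([0.3]))


@pytest.fixture(scope="module")
def tiny_training_problem():
    rng = np.random.default_rng(2)
    n_genes, n_dis = 20, 5
    A = np.zeros((25, 25))
    A[:n_genes, :n_genes] = _random_symmetric(n_genes, rng, 0.2)
    gd = rng.random((n_genes, n_dis)) < 0.25
    A[:n_genes, n_genes:] = gd
    A[n_genes:, :n_genes] = gd.T
    graph = _hetero_gd(A, n_genes)
    X = rng.standard_normal((25, 6))
    pos = [(int(g), int(d)) for g, d in zip(*np.nonzero(gd))]
    neg = [(int(g), int(d)) for g, d in zip(*np.nonzero(~gd))][: len(pos)]
    return graph, X, pos, neg


class TestTrain:
    def test_loss_trend_downward(self, tiny_training_problem):
        graph, X, pos, neg = tiny_training_problem
        hyper = GCNHyper(epochs=200, hidden=16, c_sae=16)
        _, hist = train(graph, X, pos, neg, hyper, seed=7)
        assert len(hist) == 200
        assert np.mean(hist[-10:]) < np.mean(hist[:10])
        assert hist[-1] < hist[0]

    def test_bit_reproducible(self, tiny_training_problem):
        graph, X, pos, neg = tiny_training_problem
        hyper = GCNHyper(epochs=30, hidden=16)
        _, h1 = train(graph, X, pos, neg, hyper, seed=9, strict=False)
        _, h2 = train(graph, X, pos, neg, hyper, seed=9, strict=False)
        assert h1 == h2

    def test_inference_is_deterministic_without_dropout(self, tiny_training_problem):
        graph, X, pos, neg = tiny_training_problem
        model, _ = train(graph, X, pos, neg, GCNHyper(epochs=20, hidden=16),
                         seed=3, strict=False)
        s1 = gcn.predict_scores(model, graph, X, pos)
        s2 = gcn.predict_scores(model, graph, X, pos)
        np.testing.assert_array_equal(s1, s2)
        assert ((s1 > 0) & (s1 < 1)).all()

    def test_off_grid_hyper_rejected_when_strict(self, tiny_training_problem):
        graph, X, pos, neg = tiny_training_problem
        with pytest.raises(ValueError, match="grid"):
            train(graph, X, pos, neg, GCNHyper(epochs=123), seed=0)

    def test_off_grid_allowed_when_not_strict(self, tiny_training_problem):
        graph, X, pos, neg = tiny_training_problem
        _, hist = train(graph, X, pos, neg, GCNHyper(epochs=5, hidden=16),
                        seed=0, strict=False)
        assert len(hist) == 5

    def test_empty_positive_set_rejected(self, tiny_training_problem):
        graph, X, _, neg = tiny_training_problem
        with pytest.raises(ValueError, match="positive"):
            train(graph, X, [], neg, GCNHyper(epochs=10), seed=0, strict=False)

    def test_overlapping_pos_neg_rejected(self, tiny_training_problem):
        graph, X, pos, _ = tiny_training_problem
        with pytest.raises(ValueError, match="overlap"):
            train(graph, X, pos, pos[:2], GCNHyper(epochs=10), seed=0, strict=False)


def test_model_checkpoint_arrays_round_trip(tiny_training_problem):
    graph, X, pos, neg = tiny_training_problem
    hyper = GCNHyper(epochs=10, hidden=16, mode="chebyshev")
    model, _ = train(graph, X, pos, neg, hyper, seed=5, strict=False)
    back = gcn.model_from_arrays(gcn.model_arrays(model), hyper)
    s1 = gcn.predict_scores(model, graph, X, pos)
    s2 = gcn.predict_scores(back, graph, X, pos)
    np.testing.assert_array_equal(s1, s2)
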