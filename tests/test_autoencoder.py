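import numpy as np
import pytest
from scipy.special import expit, logit

import patientrep as pr
from patientrep.autoencoder import save_sda, load_sda


class TestMaskCorrupt:
    def test_zero_fraction_leaves_input_unchanged(self, rng):
        x = rng.random(20)
        assert np.array_equal(pr.mask_corrupt(x, 0.0, rng), x)

    def test_full_corruption_zeroes_everything(self, rng):
        x = rng.random(20) + 0.1
        assert np.all(pr.mask_corrupt(x, 1.0, rng) == 0)

    def test_exactly_round_nu_d_coordinates_masked(self, rng):
        x = np.ones(1000)
        corrupted = pr.mask_corrupt(x, 0.05, rng)
        assert int((corrupted == 0).sum()) == 50

    def test_mask_positions_uniform_over_coordinates(self):
        rng = np.random.default_rng(0)
        d, draws = 100, 4000
        hits = np.zeros(d)
        corrupted = pr.mask_corrupt(np.ones((draws, d)), 0.05, rng)
        hits = (corrupted == 0).mean(axis=0)
        assert np.all(np.abs(hits - 0.05) < 0.01)

    def test_bernoulli_mode_masks_at_rate_nu(self):
        rng = np.random.default_rng(0)
        corrupted = pr.mask_corrupt(np.ones((2000, 50)), 0.3, rng, masking="bernoulli")
        assert (corrupted == 0).mean() == pytest.approx(0.3, abs=0.01)

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            pr.mask_corrupt(np.ones(5), 1.5, rng)

    def test_input_not_mutated(self, rng):
        x = np.ones(50)
        pr.mask_corrupt(x, 0.5, rng)
        assert np.all(x == 1)


class TestEncodeDecode:
    def test_zero_parameters_give_one_half(self):
        layer = pr.AutoencoderLayer(np.zeros((3, 4)), np.zeros(3), np.zeros(4))
        assert np.allclose(pr.encode(layer, np.ones(4)), 0.5)
        assert np.allclose(pr.decode(layer, np.ones(3)), 0.5)

    def test_saturated_bias(self):
        layer = pr.AutoencoderLayer(np.zeros((1, 1)), np.array([-100.0]), np.zeros(1))
        assert pr.encode(layer, np.ones(1))[0] < 1e-20

    def test_matches_direct_formula(self, rng, random_layer):
        x = rng.random(4)
        y = pr.encode(random_layer, x)
        assert np.allclose(y, expit(random_layer.W @ x + random_layer.b))
        z = pr.decode(random_layer, y)
        assert np.allclose(z, expit(random_layer.W.T @ y + random_layer.b_prime))

    def test_tied_weight_symmetry(self, rng, random_layer):
        """decode == encode of the transposed layer with swapped biases."""
        y = rng.random(5)
        swapped = pr.AutoencoderLayer(
            random_layer.W.T, random_layer.b_prime, random_layer.b
        )
        assert np.allclose(pr.decode(random_layer, y), pr.encode(swapped, y))

    def test_dimension_mismatch_rejected(self, random_layer):
        with pytest.raises(ValueError):
            pr.encode(random_layer, np.ones(3))
        with pytest.raises(ValueError):
            pr.decode(random_layer, np.ones(4))


class TestCrossEntropy:
    def test_uniform_closed_form(self):
        assert pr.cross_entropy(
            np.array([0.5, 0.5]), np.array([0.5, 0.5])
        ) == pytest.approx(2 * np.log(2))

    def test_binary_closed_form(self):
        val = pr.cross_entropy(np.array([1.0, 0.0]), np.array([0.9, 0.1]))
        assert val == pytest.approx(-2 * np.log(0.9))

    def test_minimized_at_z_equals_x(self, rng):
        x = rng.uniform(0.1, 0.9, size=6)
        at_x = pr.cross_entropy(x, x)
        for _ in range(200):
            z = rng.uniform(0.01, 0.99, size=6)
            assert pr.cross_entropy(x, z) >= at_x - 1e-12

    def test_boundary_reconstruction_rejected(self):
        with pytest.raises(ValueError):
            pr.cross_entropy(np.array([0.5]), np.array([1.0]))


class TestLayerGradients:
    def test_zero_bprime_gradient_at_perfect_reconstruction(self):
        # W = 0 makes z = sigmoid(b'); set b' = logit(x) so z == x exactly
        x = np.array([0.3, 0.6, 0.8])
        layer = pr.AutoencoderLayer(np.zeros((2, 3)), np.zeros(2), logit(x))
        batch = np.tile(x, (4, 1))
        grads = pr.layer_gradients(layer, batch, corrupted=batch)
        assert np.allclose(grads.b_prime, 0.0, atol=1e-12)

    def test_tied_gradient_equals_sum_of_untied_partials(self, rng, random_layer):
        """Oracle: treat encoder and decoder matrices as independent, compute
        each partial separately, and add the decoder partial's transpose."""
        X = rng.random((6, 4))
        Xc = pr.mask_corrupt(X, 0.25, np.random.default_rng(5))
        grads = pr.layer_gradients(random_layer, X, corrupted=Xc)

        W, b, bp = random_layer.W, random_layer.b, random_layer.b_prime
        n = X.shape[0]
        Y = expit(Xc @ W.T + b)
        Z = expit(Y @ W + bp)
        dZ = (Z - X) / n
        g_dec = Y.T @ dZ  # partial w.r.t. the decoder matrix W_dec = W
        dY = dZ @ W.T
        dY_pre = dY * Y * (1 - Y)
        g_enc = dY_pre.T @ Xc  # partial w.r.t. the encoder matrix
        assert np.allclose(grads.W, g_enc + g_dec, atol=1e-12)

    def test_finite_difference_agreement(self, rng):
        layer = pr.AutoencoderLayer(
            rng.normal(scale=0.5, size=(4, 5)),
            rng.normal(scale=0.2, size=4),
            rng.normal(scale=0.2, size=5),
        )
        X = rng.random((5, 5))
        Xc = pr.mask_corrupt(X, 0.2, np.random.default_rng(9))
        grads = pr.layer_gradients(layer, X, corrupted=Xc)

        def loss():
            Y = expit(Xc @ layer.W.T + layer.b)
            zpre = Y @ layer.W + layer.b_prime
            return float(np.mean(np.sum(np.logaddexp(0, zpre) - X * zpre, axis=1)))

        eps = 1e-6
        for arr, g in ((layer.W, grads.W), (layer.b, grads.b), (layer.b_prime, grads.b_prime)):
            flat = arr.reshape(-1)
            for idx in range(flat.size):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - g.reshape(-1)[idx]) <= 1e-5 * max(1.0, abs(fd))

    def test_empty_batch_rejected(self, random_layer):
        with pytest.raises(ValueError):
            pr.layer_gradients(random_layer, np.empty((0, 4)), nu=0.1,
                               rng=np.random.default_rng(0))


class TestTrainLayer:
    def test_loss_decreases_on_synthetic_matrix(self):
        rng = np.random.default_rng(0)
        X = rng.random((200, 50))
        cfg = pr.TrainConfig(hidden_units=20, corruption=0.1, n_epochs=10, seed=0)
        _, trace = pr.train_layer(X, cfg)
        assert trace[-1] < trace[0]

    def test_overcomplete_noiseless_layer_reaches_entropy_floor(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.1, 0.9, size=(6, 4))
        floor = float(np.mean(np.sum(
            -(X * np.log(X) + (1 - X) * np.log1p(-X)), axis=1)))
        cfg = pr.TrainConfig(
            hidden_units=16, corruption=0.0, n_epochs=2000,
            learning_rate=1.0, batch_size=6, seed=0,
        )
        _, trace = pr.train_layer(X, cfg)
        assert trace[-1] <= floor * 1.05

    def test_seeded_determinism(self, rng):
        X = rng.random((40, 10))
        cfg = pr.TrainConfig(hidden_units=8, corruption=0.2, n_epochs=5, seed=7)
        layer1, _ = pr.train_layer(X, cfg)
        layer2, _ = pr.train_layer(X, cfg)
        assert np.array_equal(layer1.W, layer2.W)
        assert np.array_equal(layer1.b, layer2.b)
        assert np.array_equal(layer1.b_prime, layer2.b_prime)

    def test_full_batch_small_lr_loss_non_increasing(self, rng):
        X = rng.random((20, 8))
        cfg = pr.TrainConfig(
            hidden_units=6, corruption=0.0, n_epochs=30,
            learning_rate=1e-3, batch_size=20, seed=0,
        )
        _, trace = pr.train_layer(X, cfg)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_unscaled_input_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            pr.train_layer(np.array([[2.0, 0.0]]), pr.TrainConfig(hidden_units=2))


class TestStack:
    def test_dimensions_chain_and_output_dim(self, rng):
        X = rng.random((30, 12))
        cfg = pr.TrainConfig(n_layers=3, hidden_units=7, n_epochs=2, seed=0)
        model, traces = pr.fit_stack(X, cfg)
        assert model.output_dim == 7 and len(model.layers) == 3
        assert [l.d_in for l in model.layers] == [12, 7, 7]
        assert len(traces) == 3

    def test_empty_stack_transform_is_identity(self, rng):
        X = rng.random((5, 4))
        model, _ = pr.fit_stack(X, pr.TrainConfig(n_layers=0, hidden_units=3))
        assert np.array_equal(model.transform(X), X)

    def test_second_layer_trains_on_clean_codes(self, rng):
        """Reproduce the greedy procedure manually: layer 2's parameters must
        equal a layer trained on encode(layer1, X) with no interface
        corruption."""
        X = rng.random((25, 6))
        cfg = pr.TrainConfig(n_layers=2, hidden_units=5, corruption=0.3,
                             n_epochs=4, seed=13)
        model, _ = pr.fit_stack(X, cfg)
        seeds = np.random.SeedSequence(cfg.seed).spawn(2)
        layer1, _ = pr.train_layer(X, cfg, rng=np.random.default_rng(seeds[0]))
        clean_codes = pr.encode(layer1, X)
        layer2, _ = pr.train_layer(clean_codes, cfg, rng=np.random.default_rng(seeds[1]))
        assert np.array_equal(model.layers[0].W, layer1.W)
        assert np.array_equal(model.layers[1].W, layer2.W)

    def test_transform_equals_manual_encoder_fold(self, rng):
        X = rng.random((6, 9))
        model, _ = pr.fit_stack(X, pr.TrainConfig(n_layers=3, hidden_units=4,
                                                  n_epochs=2, seed=0))
        H = X
        for layer in model.layers:
            H = pr.encode(layer, H)
        assert np.allclose(model.transform(X), H)

    def test_transform_entries_strictly_inside_unit_interval(self, rng):
        X = rng.random((10, 6))
        model, _ = pr.fit_stack(X, pr.TrainConfig(n_layers=2, hidden_units=4,
                                                  n_epochs=2, seed=0))
        out = model.transform(X)
        assert out.min() > 0 and out.max() < 1

    def test_row_permutation_permutes_output(self, rng):
        X = rng.random((8, 5))
        model, _ = pr.fit_stack(X, pr.TrainConfig(n_layers=2, hidden_units=3,
                                                  n_epochs=2, seed=0))
        perm = rng.permutation(8)
        assert np.allclose(model.transform(X[perm]), model.transform(X)[perm])

    def test_estimator_interface_and_serialization(self, rng, tmp_path):
        X = rng.random((30, 10))
        est = pr.StackedDenoisingAutoencoder(
            n_layers=2, hidden_units=6, n_epochs=3, random_state=0
        ).fit(X)
        out = est.transform(X)
        assert out.shape == (30, 6)
        save_sda(est.model_, tmp_path / "model")
        loaded = load_sda(tmp_path / "model")
        assert np.allclose(loaded.transform(X), out)

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.random((10, 4))
        model, _ = pr.fit_stack(X, pr.TrainConfig(n_layers=1, hidden_units=3,
                                                  n_epochs=1, seed=0))
        with pytest.raises(ValueError):
            model.transform(rng.random((3, 5)))


def test_denoising_beats_column_mean_on_block_correlated_data():
    """Masked-entry imputation: a layer trained with masking noise on
    block-correlated data fills in deliberately blanked entries better than
    the per-column mean."""
    rng = np.random.default_rng(7)
    n, d, n_blocks = 600, 100, 4
    h = rng.random((n, n_blocks)) < 0.5
    G = np.zeros((n_blocks, d))
    for k in range(n_blocks):
        G[k, k * 25 : (k + 1) * 25] = 1.0
    X = np.clip(0.15 + 0.7 * (h @ G) + rng.normal(0, 0.05, (n, d)), 0, 1)
    Xtr, Xte = X[:500], X[500:]
    layer, _ = pr.train_layer(
        Xtr, pr.TrainConfig(hidden_units=30, corruption=0.3, n_epochs=60, seed=0)
    )
    mask = np.random.default_rng(42).random(Xte.shape) < 0.2
    Xm = Xte.copy()
    Xm[mask] = 0.0
    Z = pr.decode(layer, pr.encode(layer, Xm))
    mse_da = np.mean((Z[mask] - Xte[mask]) ** 2)
    col_mean = Xtr.mean(axis=0)
    mse_cm = np.mean((np.broadcast_to(col_mean, Xte.shape)[mask] - Xte[mask]) ** 2)
    assert mse_da < mse_cm
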