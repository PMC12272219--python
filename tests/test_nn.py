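"""The 3D convolutional base model: architecture contracts, gradient
correctness against finite differences, determinism, masking, serialization."""

import numpy as np
import pytest

from metamatch.nn.network import pooled_extent
from metamatch.sfcn import (SFCNConfig, SFCNRegressor, TrainConfig, build_model,
                            load_model, masked_mse, save_model, train_network,
                            _masked_mse_grad)


class TestArchitecture:
    @pytest.mark.parametrize("shape,blocks,expected", [
        ((160, 192, 160), 6, (5, 6, 5)),    # full-scale: 5 poolings
        ((32, 40, 32), 4, (4, 5, 4)),       # desk-scale: 3 poolings
    ])
    def test_pre_averaging_extent_matches_floor_halving(self, shape, blocks, expected):
        assert pooled_extent(shape, blocks - 1) == expected

    def test_extent_oracle_on_random_configs(self, rng):
        """Repeated floor(x/2), applied B−1 times, for arbitrary valid configs."""
        for _ in range(20):
            shape = tuple(int(rng.integers(8, 200)) for _ in range(3))
            halvings = int(rng.integers(1, 4))
            ref = []
            for s in shape:
                for _ in range(halvings):
                    s //= 2
                ref.append(s)
            assert pooled_extent(shape, halvings) == tuple(ref)

    def test_single_output_no_icv(self, rng):
        cfg = SFCNConfig(input_shape=(8, 8, 8), channels=(2, 3),
                         kernel_sizes=(3, 1), n_outputs=1, use_icv=False)
        net = build_model(cfg, seed=0)
        out = net.forward(rng.standard_normal((2, 8, 8, 8)))
        assert out.shape == (2, 1)

    def test_spatial_collapse_rejected(self):
        with pytest.raises(ValueError, match="collapses"):
            SFCNConfig(input_shape=(4, 4, 4), channels=(2, 2, 2, 2),
                       kernel_sizes=(3, 3, 3, 1))

    def test_output_width_equals_n_outputs(self, rng):
        for p in (1, 3, 7):
            cfg = SFCNConfig(input_shape=(8, 8, 8), channels=(2, 3),
                             kernel_sizes=(3, 1), n_outputs=p, use_icv=True)
            net = build_model(cfg, seed=0)
            out = net.forward(rng.standard_normal((3, 8, 8, 8)),
                              rng.standard_normal(3))
            assert out.shape == (3, p)


@pytest.fixture(scope="module")
def small_net():
    cfg = SFCNConfig(input_shape=(8, 10, 8), channels=(3, 4),
                     kernel_sizes=(3, 1), dropout_rate=0.3, n_outputs=2)
    return build_model(cfg, seed=7)


class TestForwardContracts:

    def test_eval_mode_is_deterministic(self, small_net, rng):
        X = rng.standard_normal((4, 8, 10, 8))
        icv = rng.standard_normal(4)
        a = small_net.predict(X, icv)
        b = small_net.predict(X, icv)
        np.testing.assert_array_equal(a, b)

    def test_batch_independence_in_eval_mode(self, small_net, rng):
        X = rng.standard_normal((5, 8, 10, 8)).astype(np.float32)
        icv = rng.standard_normal(5).astype(np.float32)
        full = small_net.predict(X, icv)
        row = small_net.predict(X[2:3], icv[2:3])
        np.testing.assert_allclose(row[0], full[2], rtol=1e-5)

    def test_nonfinite_voxel_rejected(self, small_net):
        X = np.zeros((1, 8, 10, 8))
        X[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            small_net.forward(X, np.zeros(1))

    def test_shape_mismatch_rejected(self, small_net, rng):
        with pytest.raises(ValueError, match="spatial shape"):
            small_net.forward(rng.standard_normal((1, 8, 8, 8)), np.zeros(1))


class TestGradients:
    def _setup(self, rng, dropout=0.0):
        cfg = SFCNConfig(input_shape=(8, 8, 8), channels=(3, 4),
                         kernel_sizes=(3, 1), dropout_rate=dropout, n_outputs=2)
        net = build_model(cfg, seed=1, dtype=np.float64)
        X = rng.standard_normal((4, 8, 8, 8))
        icv = rng.standard_normal(4)
        Y = rng.standard_normal((4, 2))
        return net, X, icv, Y

    def test_matches_finite_differences(self, rng):
        net, X, icv, Y = self._setup(rng)
        mask = np.array([[1, 1], [1, 0], [0, 1], [1, 1]], bool)

        def loss():
            p = net.forward(X, icv, training=True, rng=np.random.default_rng(0))
            return masked_mse(p, Y, mask)

        preds = net.forward(X, icv, training=True, rng=np.random.default_rng(0))
        net.backward(_masked_mse_grad(preds, Y, mask))
        eps = 1e-5
        for layer in net.trainable_layers():
            for name, P in layer.params.items():
                idx = tuple(rng.integers(0, s) for s in P.shape)
                analytic = layer.grads[name][idx]
                orig = P[idx]
                P[idx] = orig + eps
                lp = loss()
                P[idx] = orig - eps
                lm = loss()
                P[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-9)

    def test_masked_entries_contribute_no_gradient(self, rng):
        """The head-weight gradient for an all-masked output column is zero."""
        net, X, icv, Y = self._setup(rng)
        mask = np.ones((4, 2), bool)
        mask[:, 1] = False
        preds = net.forward(X, icv, training=True, rng=np.random.default_rng(0))
        net.backward(_masked_mse_grad(preds, Y, mask))
        np.testing.assert_array_equal(net.head.grads["W"][:, 1], 0.0)
        np.testing.assert_array_equal(net.head.grads["b"][1], 0.0)


class TestTraining:
    def test_zero_epoch_budget_rejected(self):
        with pytest.raises(ValueError, match="max_epochs"):
            TrainConfig(max_epochs=0)

    def test_empty_training_set_rejected(self, rng):
        net = build_model(SFCNConfig(input_shape=(8, 8, 8), channels=(2, 2),
                                     kernel_sizes=(3, 1), use_icv=False), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_network(net, rng.standard_normal((4, 8, 8, 8, 1)), None,
                          rng.standard_normal((4, 1)), np.ones((4, 1), bool),
                          np.array([], int), np.arange(4), TrainConfig(max_epochs=1))

    def test_all_masked_column_is_ignored(self, rng):
        """Training proceeds when one phenotype column is fully unobserved."""
        cfg = SFCNConfig(input_shape=(8, 8, 8), channels=(2, 2),
                         kernel_sizes=(3, 1), dropout_rate=0.0, n_outputs=2,
                         use_icv=False)
        net = build_model(cfg, seed=0)
        X = rng.standard_normal((12, 8, 8, 8, 1)).astype(np.float32)
        Y = rng.standard_normal((12, 2))
        mask = np.ones((12, 2), bool)
        mask[:, 1] = False
        log = train_network(net, X, None, Y, mask, np.arange(10),
                            np.arange(10, 12), TrainConfig(max_epochs=2, seed=0))
        assert np.isfinite(log[0]["train_loss"])


class TestSerialization:
    def test_save_load_forward_identical(self, tiny_base, tiny_bench, tmp_path):
        ds = tiny_bench.dataset
        X = ds.volumes[:3]
        icv = ds.icv[:3]
        path = tmp_path / "model.npz"
        save_model(tiny_base, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(tiny_base.predict(X, icv),
                                      loaded.predict(X, icv))

    def test_corrupted_file_errors(self, tmp_path):
        path = tmp_path / "bad.npz"
        path.write_bytes(b"not a model")
        with pytest.raises(ValueError, match="unreadable"):
            load_model(path)

    def test_version_mismatch_errors(self, tiny_base, tmp_path, monkeypatch):
        import metamatch.sfcn as sfcn_mod

        path = tmp_path / "model.npz"
        save_model(tiny_base, path)
        monkeypatch.setattr(sfcn_mod, "_FORMAT_VERSION", 99)
        with pytest.raises(ValueError, match="version"):
            load_model(path)

    def test_wrong_input_shape_rejected_at_forward(self, tiny_base, tmp_path, rng):
        path = tmp_path / "model.npz"
        save_model(tiny_base, path)
        loaded = load_model(path)
        with pytest.raises(ValueError, match="spatial shape"):
            loaded.predict(rng.standard_normal((1, 8, 8, 8)), np.ones(1))


class TestPretrainingRecovery:
    def test_recovers_noiseless_latent_phenotypes(self, rng):
        """n=300, 16³ volumes, 4 noiseless latent-readout phenotypes: held-out
        Pearson r > 0.8 for at least 3 of 4 after pretraining."""
        from metamatch.benchmark import _normalized_volumes
        from metamatch.metrics import pearson
        from metamatch.synthetic import SyntheticConfig, generate

        cfg = SyntheticConfig(n=300, grid_shape=(16, 16, 16), n_latents=4,
                              blob_radius_range=(2.0, 3.5),
                              phenotype_noise_var=0.0, seed=7)
        ds = generate(cfg)
        vols = _normalized_volumes(ds.volumes)
        train, test = np.arange(240), np.arange(240, 300)
        model = SFCNRegressor(
            config=SFCNConfig(input_shape=(16, 16, 16)),
            train_config=TrainConfig(lr=0.03, max_epochs=12, lr_step=6, seed=3))
        model.fit(vols[train], ds.phenotypes.values[train], icv=ds.icv[train])
        preds = model.predict(vols[test], ds.icv[test])
        rs = [pearson(ds.phenotypes.values[test, j], preds[:, j]) for j in range(4)]
        assert sum(r > 0.8 for r in rs) >= 3, rs
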