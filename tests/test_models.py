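"""Autoencoder variants: architecture, training, pretraining, penalties."""

import numpy as np
import pytest

from spikeae.datasets import LabeledSpikeSet
from spikeae.models import (
    AEConfig,
    SpikeAutoencoder,
    TrainedEncoder,
    build_model,
    contractive_loss,
    greedy_pretrain,
    orthogonal_penalties,
    pca_ae_embed,
    variant_config,
)
from spikeae.nn import (
    LSTM,
    Dense,
    contractive_forward_backward,
    encoder_jacobians,
)


class TestArchitecture:
    def test_deep_variant_has_17_layers(self):
        model = build_model(variant_config("deep", input_dim=79))
        assert model.network.n_layers == 17

    def test_shallow_widths_and_mirror(self):
        model = build_model(variant_config("shallow", input_dim=79))
        widths = [l.n_out for l in model.network.layers]
        assert widths == [60, 40, 20, 2, 20, 40, 60, 79]

    def test_tied_decoder_is_transpose_at_init(self):
        model = build_model(variant_config("tied", input_dim=79))
        tied = [l for l in model.network.layers if l.tied_to is not None]
        assert len(tied) == 9
        for l in tied:
            np.testing.assert_array_equal(l.W, l.tied_to.W_own.T)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            AEConfig(encoder_layers=[40, 60, 20]).validate()  # not decreasing
        with pytest.raises(ValueError):
            AEConfig(encoder_layers=[60, 40], code_size=40).validate()
        with pytest.raises(ValueError):
            AEConfig(learning_rate=0.0).validate()
        with pytest.raises(ValueError):
            variant_config("vae")


class TestTraining:
    def test_single_repeated_waveform_reconstructed(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.2, 0.8, size=79)
        sp = LabeledSpikeSet(np.tile(w, (64, 1)), 24000.0)
        res = SpikeAutoencoder(sp, "shallow", epochs=200).fit(seed=0)
        rec = res.reconstruct(sp)
        rms = np.sqrt(np.mean((rec - sp.waveforms) ** 2))
        assert rms < 0.05

    def test_loss_history_finite_and_improves(self, prepped_spikes):
        res = SpikeAutoencoder(prepped_spikes, "shallow", epochs=10).fit(seed=0)
        h = np.asarray(res.loss_history)
        assert len(h) == 10
        assert np.isfinite(h).all()
        assert h.min() <= h[0]

    def test_identical_seed_gives_identical_history(self, prepped_spikes):
        a = SpikeAutoencoder(prepped_spikes, "shallow", epochs=3).fit(seed=4)
        b = SpikeAutoencoder(prepped_spikes, "shallow", epochs=3).fit(seed=4)
        np.testing.assert_array_equal(a.loss_history, b.loss_history)

    def test_tied_constraint_maintained_during_training(self, prepped_spikes):
        violations = []

        def check(net):
            for l in net.layers:
                if l.tied_to is not None:
                    violations.append(np.abs(l.W - l.tied_to.W_own.T).max())

        SpikeAutoencoder(prepped_spikes, "tied", epochs=2).fit(
            seed=0, step_callback=check
        )
        assert violations and max(violations) == 0.0


class TestEncode:
    def test_shape_order_and_range(self, prepped_spikes):
        res = SpikeAutoencoder(prepped_spikes, "shallow", epochs=5).fit(seed=0)
        f = res.encode(prepped_spikes)
        assert f.features.shape == (prepped_spikes.n_spikes, 2)
        # deterministic at inference
        f2 = res.encode(prepped_spikes)
        np.testing.assert_array_equal(f.features, f2.features)
        # tanh code range
        assert (np.abs(f.features) <= 1.0).all()

    def test_untrained_model_refuses_to_encode(self, prepped_spikes):
        model = build_model(variant_config("shallow"))
        with pytest.raises(RuntimeError):
            model.encode(prepped_spikes)

    def test_checkpoint_roundtrip(self, tmp_path, prepped_spikes):
        res = SpikeAutoencoder(prepped_spikes, "shallow", epochs=3).fit(seed=0)
        path = tmp_path / "model.npz"
        res.save(path)
        back = TrainedEncoder.load(path)
        np.testing.assert_array_equal(
            back.encode(prepped_spikes).features,
            res.encode(prepped_spikes).features,
        )

    def test_summary_mentions_variant_and_layers(self, prepped_spikes):
        res = SpikeAutoencoder(prepped_spikes, "shallow", epochs=2).fit(seed=0)
        s = res.summary()
        assert "shallow" in s and "7" in s


class TestGreedyPretrain:
    def test_first_stage_shapes(self, prepped_spikes):
        cfg = variant_config("pretrained", input_dim=79, pretrain_epochs=1)
        store = greedy_pretrain(cfg, prepped_spikes, seed=0)
        s0 = store["stages"][0]
        assert s0["W_enc"].shape == (79, 70)
        assert s0["W_dec"].shape == (70, 79)
        assert s0["b_enc"].shape == (70,)
        assert s0["code_dim"] == 70

    def test_assembled_init_matches_model_shapes(self, prepped_spikes):
        cfg = variant_config("pretrained", input_dim=79, pretrain_epochs=1)
        store = greedy_pretrain(cfg, prepped_spikes, seed=0)
        model = build_model(cfg)
        model.load_initial_parameters(store)  # raises on any shape mismatch
        assert len(store["init"]) == len(model.network.layers)

    def test_pretraining_lowers_first_epoch_loss(self, prepped_spikes):
        pre, rnd = [], []
        for seed in range(5):
            cfg_p = variant_config("pretrained", epochs=1, pretrain_epochs=10)
            pre.append(
                TrainedEncoder.build(cfg_p, seed=seed)
                .fit(prepped_spikes, seed=seed)
                .loss_history[0]
            )
            cfg_r = variant_config("deep", epochs=1)
            rnd.append(
                TrainedEncoder.build(cfg_r, seed=seed)
                .fit(prepped_spikes, seed=seed)
                .loss_history[0]
            )
        assert np.median(pre) <= np.median(rnd)


class TestContractive:
    def test_zero_lambda_equals_plain_reconstruction_loss(self, rng):
        X = rng.uniform(size=(8, 10))
        R = rng.uniform(size=(8, 10))
        J = rng.normal(size=(8, 10, 2))
        base = contractive_loss(X, R, np.zeros_like(J), 0.0)
        assert contractive_loss(X, R, J, 0.0) == pytest.approx(base)

    def test_penalty_monotone_in_lambda(self, rng):
        X = rng.uniform(size=(8, 10))
        R = rng.uniform(size=(8, 10))
        J = rng.normal(size=(8, 10, 2))
        vals = [contractive_loss(X, R, J, lam) for lam in (0.0, 0.1, 1.0)]
        assert vals[0] <= vals[1] <= vals[2]

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            contractive_loss(np.zeros((2, 3)), np.zeros((2, 3)), np.zeros((2, 3, 1)), -1.0)

    def test_analytic_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        layers = [Dense(6, 5, "relu", rng), Dense(5, 3, "tanh", rng)]
        X = rng.uniform(0.1, 0.9, size=(4, 6))
        J = encoder_jacobians(layers, X)

        def enc(x):
            a = x[None, :]
            for l in layers:
                a = l.act(a @ l.W + l.b)
            return a[0]

        h = 1e-6
        for s in range(4):
            fd = np.zeros((6, 3))
            for i in range(6):
                xp, xm = X[s].copy(), X[s].copy()
                xp[i] += h
                xm[i] -= h
                fd[i] = (enc(xp) - enc(xm)) / (2 * h)
            rel = np.abs(fd - J[s]).max() / (np.abs(fd).max() + 1e-12)
            assert rel <= 1e-4

    def test_penalty_gradient_matches_finite_differences(self):
        # the Hutchinson-probe training gradient, checked against numeric
        # differentiation of the same probe
        rng = np.random.default_rng(0)
        layers = [Dense(5, 4, "relu", rng), Dense(4, 2, "tanh", rng)]
        X = rng.uniform(0.1, 0.9, size=(3, 5))
        lam, probe_seed = 0.5, 42

        def penalty():
            r = np.random.default_rng(probe_seed)
            A, V = X, r.standard_normal(X.shape)
            for l in layers:
                Z = A @ l.W + l.b
                A2 = l.act(Z)
                V = l.act_prime(Z, A2) * (V @ l.W)
                A = A2
            return lam * float(np.sum(V * V))

        for l in layers:
            l.zero_grad()
        val = contractive_forward_backward(
            layers, X, np.random.default_rng(probe_seed), lam
        )
        assert val == pytest.approx(penalty())
        h = 1e-6
        for l in layers:
            for _, p, g in l.params():
                flat_p, flat_g = p.ravel(), g.ravel()
                for i in range(0, flat_p.size, max(1, flat_p.size // 5)):
                    orig = flat_p[i]
                    flat_p[i] = orig + h
                    lp = penalty()
                    flat_p[i] = orig - h
                    lm = penalty()
                    flat_p[i] = orig
                    fd = (lp - lm) / (2 * h)
                    assert abs(fd - flat_g[i]) <= 1e-4 * max(1.0, abs(fd))

    def test_trained_contractive_less_sensitive_than_plain(self, prepped_spikes):
        cj, dj = [], []
        for seed in range(3):
            mc = SpikeAutoencoder(prepped_spikes, "contractive", epochs=20).fit(seed=seed)
            md = SpikeAutoencoder(prepped_spikes, "deep", epochs=20).fit(seed=seed)
            cj.append(mc.mean_jacobian_norm(prepped_spikes))
            dj.append(md.mean_jacobian_norm(prepped_spikes))
        assert np.median(cj) < np.median(dj)


class TestOrthogonalPenalties:
    def test_orthonormal_matrix_zero_penalty(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(5, 3)))
        p_orth, _ = orthogonal_penalties([Q], rng.normal(size=(10, 3)))
        assert p_orth == pytest.approx(0.0, abs=1e-12)

    def test_uncorrelated_codes_zero_decorrelation(self):
        codes = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        _, p_dec = orthogonal_penalties([np.eye(2)], codes)
        assert p_dec == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_matrix_arithmetic(self, rng):
        W = rng.normal(size=(5, 3))
        codes = rng.normal(size=(20, 3))
        p_orth, p_dec = orthogonal_penalties([W], codes)
        G = W.T @ W - np.eye(3)
        assert p_orth == pytest.approx(float((G**2).sum()))
        C = np.cov(codes, rowvar=False)
        expect = float((C**2).sum() - (np.diag(C) ** 2).sum())
        assert p_dec == pytest.approx(expect)

    def test_single_sample_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            orthogonal_penalties([np.eye(2)], rng.normal(size=(1, 2)))


class TestPcaHybrid:
    def test_embeds_to_2d_with_ordered_orthogonal_axes(self, prepped_spikes):
        res = SpikeAutoencoder(prepped_spikes, "pca_hybrid", epochs=10).fit(seed=0)
        assert res.encode(prepped_spikes).d == 20
        f = pca_ae_embed(res, prepped_spikes)
        assert f.d == 2
        comps = res.fitted_postmap.components_
        assert abs(comps[0] @ comps[1]) < 1e-9
        v = f.features.var(axis=0)
        assert v[0] >= v[1]

    def test_wrong_variant_rejected(self, prepped_spikes):
        res = SpikeAutoencoder(prepped_spikes, "shallow", epochs=2).fit(seed=0)
        with pytest.raises(ValueError):
            pca_ae_embed(res, prepped_spikes)


class TestLSTM:
    def test_bptt_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        layer = LSTM(2, 3, rng, return_sequences=True)
        X = rng.normal(size=(2, 5, 2))

        def loss():
            return float(np.sum(layer.forward(X) ** 2))

        out = layer.forward(X)
        layer.zero_grad()
        layer.backward(2 * out)
        h = 1e-6
        for _, p, g in layer.params():
            fp, fg = p.ravel(), g.ravel()
            for i in range(0, fp.size, max(1, fp.size // 6)):
                orig = fp[i]
                fp[i] = orig + h
                lp = loss()
                fp[i] = orig - h
                lm = loss()
                fp[i] = orig
                fd = (lp - lm) / (2 * h)
                assert abs(fd - fg[i]) <= 1e-4 * max(1.0, abs(fd))

    def test_lstm_variant_trains_and_encodes(self):
        rng = np.random.default_rng(0)
        sp = LabeledSpikeSet(rng.uniform(size=(24, 20)), 24000.0)
        cfg = variant_config(
            "lstm", input_dim=20, encoder_layers=[8, 6, 4], epochs=2, batch_size=8
        )
        res = SpikeAutoencoder(sp, cfg).fit(seed=0)
        f = res.encode(sp)
        assert f.features.shape == (24, 2)
        assert np.isfinite(res.loss_history).all()


class TestFourierVariants:
    def test_ft_and_wft_train_on_half_spectrum(self, prepped_spikes):
        for v in ("ft", "wft"):
            res = SpikeAutoencoder(prepped_spikes, v, epochs=3).fit(seed=0)
            assert res.network.layers[0].n_in == 79 // 2 + 1
            f = res.encode(prepped_spikes)
            assert f.features.shape == (prepped_spikes.n_spikes, 2)
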